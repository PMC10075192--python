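import numpy as np
import pandas as pd
import pytest

from estrkit import synthetic_data as sd
from estrkit.containers import StrGenotypeMatrix


@pytest.fixture(scope="session")
def small_panel() -> StrGenotypeMatrix:
    """60-strain, 150-locus inbred STR panel with light missingness."""
    return sd.simulate_str_panel(n_strains=60, n_loci=150, seed=11)


@pytest.fixture()
def tiny_matrix() -> StrGenotypeMatrix:
    """Hand-built 3-locus, 4-strain matrix covering het/missing cases."""
    loci = pd.DataFrame(
        {
            "locus": ["STR_a", "STR_b", "STR_c"],
            "chrom": ["I", "I", "II"],
            "pos": [100, 5000, 300],
            "end": [105, 5011, 308],
            "motif": ["AT", "ATG", "AAT"],
        }
    ).set_index("locus")
    alleles = [
        ["ATATAT", "ATAT"],          # 6, 4 bp
        ["ATGATGATGATG", "ATGATGATGATGATG", "ATGATGATGGTG"],  # 12, 15, 12 bp
        ["AATAATAAT", "AATAAT"],     # 9, 6 bp
    ]
    a1 = np.array([[0, 1, 0, -1], [0, 1, 3 - 1, 0], [0, 0, 1, 1]], dtype=np.int32)
    a2 = np.array([[0, 1, 1, -1], [0, 2, 1, 0], [0, 0, 1, 1]], dtype=np.int32)
    return StrGenotypeMatrix(
        loci=loci,
        alleles=alleles,
        a1=a1,
        a2=a2,
        passes=np.ones((3, 4), dtype=bool),
        strains=["w1", "w2", "w3", "w4"],
    )
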