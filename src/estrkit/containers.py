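"""Core in-memory containers shared by every analysis stage.

Coordinates are 1-based inclusive throughout (VCF convention); BED input is
converted on ingest.  Missing genotype calls are encoded as -1 in allele-index
arrays and as NaN in code matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "StrGenotypeMatrix",
    "ExpressionMatrix",
    "IntervalSet",
    "TransformedStrMatrix",
    "MarkerMatrix",
]


@dataclass
class StrGenotypeMatrix:
    """Diploid STR calls for a panel of (mostly homozygous, inbred) strains.

    Parameters
    ----------
    loci : DataFrame indexed by locus id with columns ``chrom``, ``pos``,
        ``end`` and ``motif``.
    alleles : per-locus list of allele sequences; position in the list is the
        allele index referenced by calls (index 0 is the reference allele).
    a1, a2 : int arrays of shape (n_loci, n_strains) holding allele indices,
        ``MISSING`` (-1) where the call is absent.
    passes : bool array of shape (n_loci, n_strains); a call is "reliable"
        only where True (VCF FILTER == PASS, broadcast per site unless a
        per-sample FT field was present).
    strains : strain names, one per column.
    """

    loci: pd.DataFrame
    alleles: list[list[str]]
    a1: np.ndarray
    a2: np.ndarray
    passes: np.ndarray
    strains: list[str]

    def __post_init__(self) -> None:
        n_loci, n_strains = self.a1.shape
        if self.a2.shape != (n_loci, n_strains) or self.passes.shape != (n_loci, n_strains):
            raise ValueError("call array shapes disagree")
        if len(self.strains) != n_strains or len(self.loci) != n_loci:
            raise ValueError("metadata dimensions disagree with call arrays")
        if len(self.alleles) != n_loci:
            raise ValueError("allele registry length disagrees with locus count")
        for i, regs in enumerate(self.alleles):
            for arr in (self.a1[i], self.a2[i]):
                called = arr[arr != MISSING]
                if called.size and called.max() >= len(regs):
                    raise ValueError(
                        f"allele index without registered allele at locus "
                        f"{self.loci.index[i]!r}"
                    )

    @property
    def n_loci(self) -> int:
        return self.a1.shape[0]

    @property
    def n_strains(self) -> int:
        return self.a1.shape[1]

    @property
    def missing(self) -> np.ndarray:
        return (self.a1 == MISSING) | (self.a2 == MISSING)

    def allele_lengths(self, locus_idx: int) -> np.ndarray:
        return np.array([len(s) for s in self.alleles[locus_idx]])

    def locus_index(self, locus_id: str) -> int:
        return int(self.loci.index.get_loc(locus_id))

    def subset_strains(self, strains: list[str]) -> "StrGenotypeMatrix":
        cols = [self.strains.index(s) for s in strains]
        return StrGenotypeMatrix(
            loci=self.loci,
            alleles=self.alleles,
            a1=self.a1[:, cols],
            a2=self.a2[:, cols],
            passes=self.passes[:, cols],
            strains=list(strains),
        )


@dataclass
class ExpressionMatrix:
    """Normalized transcript expression plus transcript coordinates.

    ``values``: transcripts x strains (float, NaN = absent).
    ``meta``: per-transcript ``gene``, ``chrom``, ``tss``, ``strand``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate transcript ids: {dups}")
        missing_meta = {"gene", "chrom", "tss", "strand"} - set(self.meta.columns)
        if missing_meta:
            raise ValueError(f"transcript metadata lacks columns: {sorted(missing_meta)}")
        if not self.meta.index.equals(self.values.index):
            self.meta = self.meta.loc[self.values.index]

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)

    @property
    def transcripts(self) -> list[str]:
        return list(self.values.index)

    def reorder_strains(self, strains: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(strains)], self.meta)


@dataclass
class IntervalSet:
    """Named genomic intervals, 1-based inclusive. Overlaps are kept as-is."""

    df: pd.DataFrame  # columns: chrom, start, end, name

    def __post_init__(self) -> None:
        bad = self.df["start"] > self.df["end"]
        if bad.any():
            raise ValueError(f"interval start > end at rows {list(self.df.index[bad])}")

    def __len__(self) -> int:
        return len(self.df)

    def overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        d = self.df
        return d[(d["chrom"] == chrom) & (d["start"] <= end) & (d["end"] >= start)]

    def covers(self, chrom: np.ndarray, pos_start: np.ndarray, pos_end: np.ndarray) -> np.ndarray:
        """Boolean mask: does any interval overlap each (chrom, start, end)?"""
        out = np.zeros(len(chrom), dtype=bool)
        for _, iv in self.df.iterrows():
            out |= (chrom == iv["chrom"]) & (pos_start <= iv["end"]) & (pos_end >= iv["start"])
        return out


@dataclass
class TransformedStrMatrix:
    """Single-code STR matrix: loci x strains, one number per call.

    ``coding_kind='genotype'``: allele index (heterozygotes reduced to the
    smaller index).  ``coding_kind='length'``: mean bp of the two allele
    copies (half-integers allowed).  NaN marks missing calls.
    """

    codes: pd.DataFrame
    coding_kind: str
    provenance: StrGenotypeMatrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.coding_kind not in ("genotype", "length"):
            raise ValueError(f"unknown coding_kind {self.coding_kind!r}")

    @property
    def strains(self) -> list[str]:
        return list(self.codes.columns)


@dataclass
class MarkerMatrix:
    """Complete markers x strains code matrix for GRM/GWA work.

    SNV codes are 0/1 (homozygous ref/alt); STR markers carry their
    transformed genotype codes.  ``meta`` has ``chrom``, ``pos``, ``source``.
    """

    codes: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.codes.isna().any().any():
            raise ValueError("marker matrix contains missing cells")
        if not self.meta.index.equals(self.codes.index):
            self.meta = self.meta.loc[self.codes.index]

    @property
    def strains(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def n_markers(self) -> int:
        return len(self.codes)
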