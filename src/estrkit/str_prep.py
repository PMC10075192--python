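"""STR call transformations and the genome-wide STR-variation trait.

Raw diploid calls become single per-strain codes in one of two factorial
codings used for association testing:

* ``genotype`` — the allele index; heterozygotes take the smaller of the two
  indices (the panel is selfing and nearly homozygous, so this loses almost
  nothing).
* ``length`` — the arithmetic mean of the two allele lengths in bp, so two
  distinct alleles of equal length collapse to one level.

The common-allele filter keeps a locus only when at least two codes each
exceed a frequency threshold (default 0.05) among non-missing strains, and
drops the strains carrying rarer codes for that locus.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import MISSING, StrGenotypeMatrix, TransformedStrMatrix

logger = logging.getLogger("estrkit")

__all__ = [
    "transform_genotypes",
    "compute_length_codes",
    "filter_common",
    "to_biallelic",
    "impute_missing",
    "derive_str_variation_trait",
]


def transform_genotypes(raw: StrGenotypeMatrix) -> TransformedStrMatrix:
    """Reduce each diploid call to a single allele-index code.

    Homozygous (a, a) -> a; heterozygous (a, b) -> min(a, b); missing -> NaN.
    """
    codes = np.minimum(raw.a1, raw.a2).astype(float)
    codes[raw.missing] = np.nan
    df = pd.DataFrame(codes, index=raw.loci.index, columns=raw.strains)
    return TransformedStrMatrix(codes=df, coding_kind="genotype", provenance=raw)


def compute_length_codes(raw: StrGenotypeMatrix) -> TransformedStrMatrix:
    """Code each call as the mean bp length of its two allele copies."""
    out = np.full(raw.a1.shape, np.nan)
    for i in range(raw.n_loci):
        lens = raw.allele_lengths(i).astype(float)
        ok = ~raw.missing[i]
        out[i, ok] = (lens[raw.a1[i, ok]] + lens[raw.a2[i, ok]]) / 2.0
    df = pd.DataFrame(out, index=raw.loci.index, columns=raw.strains)
    return TransformedStrMatrix(codes=df, coding_kind="length", provenance=raw)


def filter_common(
    codes: pd.Series | np.ndarray,
    min_freq: float = 0.05,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Apply the two-common-variants filter to one locus.

    Parameters
    ----------
    codes : per-strain codes for one locus (NaN = missing).
    min_freq : a code is "common" when its frequency among non-missing
        strains is strictly greater than this.

    Returns
    -------
    ``(keep_mask, common_codes)`` where ``keep_mask`` marks strains carrying
    a common code (missing and rare-code strains are False), or ``None``
    when fewer than two codes are common (locus rejected).
    """
    vals = np.asarray(codes, dtype=float)
    present = ~np.isnan(vals)
    n = int(present.sum())
    if n == 0:
        return None
    uniq, counts = np.unique(vals[present], return_counts=True)
    common = uniq[counts / n > min_freq]
    if len(common) < 2:
        return None
    keep = present & np.isin(vals, common)
    return keep, common


def to_biallelic(codes: TransformedStrMatrix) -> pd.DataFrame:
    """Collapse multiallelic genotype codes to 0/1 (reference / any alt).

    Non-reference codes (1, 2, 3, ...) map to 1; 0 stays 0; NaN propagates.
    Undefined for the length coding, which has no reference level.
    """
    if codes.coding_kind != "genotype":
        raise ValueError("biallelic transform requires genotype coding (no reference level in lengths)")
    return (codes.codes > 0).astype(float).where(codes.codes.notna())


def impute_missing(codes: TransformedStrMatrix, seed: int, max_missing: float = 0.5) -> TransformedStrMatrix:
    """Fill missing codes by sampling each locus's empirical code distribution.

    Deterministic given ``seed``.  Loci with a missing fraction at or above
    ``max_missing`` are refused (too little signal to impute from).
    """
    vals = codes.codes.to_numpy(copy=True)
    miss_frac = np.isnan(vals).mean(axis=1)
    over = miss_frac >= max_missing
    if over.any():
        bad = list(codes.codes.index[over])
        raise ValueError(f"missing fraction >= {max_missing} at loci: {bad}")
    rng = np.random.default_rng(seed)
    for i in range(vals.shape[0]):
        gap = np.isnan(vals[i])
        if not gap.any():
            continue
        obs = vals[i, ~gap]
        uniq, counts = np.unique(obs, return_counts=True)
        vals[i, gap] = rng.choice(uniq, size=int(gap.sum()), p=counts / counts.sum())
    df = pd.DataFrame(vals, index=codes.codes.index, columns=codes.codes.columns)
    return TransformedStrMatrix(codes=df, coding_kind=codes.coding_kind, provenance=codes.provenance)


def derive_str_variation_trait(raw: StrGenotypeMatrix) -> pd.DataFrame:
    """Per-strain genome-wide STR variation: log10(N_alt / (2 N_total)).

    N_total counts STRs with no missing genotype in the strain; N_alt counts
    alternative allele copies over both chromosomes at those STRs.  Strains
    with N_alt = 0 have an undefined (log 0) trait: they are flagged and
    excluded downstream rather than pseudocounted.
    """
    present = ~raw.missing
    n_total = present.sum(axis=0)
    if (n_total == 0).any():
        bad = [s for s, n in zip(raw.strains, n_total) if n == 0]
        raise ValueError(f"strains with no non-missing STR calls: {bad}")
    alt = ((raw.a1 > 0) & present).sum(axis=0) + ((raw.a2 > 0) & present).sum(axis=0)
    with np.errstate(divide="ignore"):
        value = np.log10(alt / (2.0 * n_total))
    undefined = alt == 0
    if undefined.any():
        logger.warning(
            "STR variation trait undefined (N_alt=0) for strains: %s",
            [s for s, u in zip(raw.strains, undefined) if u],
        )
    return pd.DataFrame(
        {
            "value": value,
            "n_total": n_total,
            "n_alt": alt,
            "undefined": undefined,
        },
        index=pd.Index(raw.strains, name="strain"),
    )
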