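"""Linkage disequilibrium and variance-explained comparisons.

LD between an eSTR (binarized to reference / any-alternative) and a SNV is
computed from per-strain single codes: the panel is selfing-homozygous, so
each strain contributes one haplotype observation.  The signed correlation is

    r = -D / sqrt(p(A) p(a) p(B) p(b)),   D = p(AB) - p(A) p(B)

with A/B the reference codes at the two markers.  Variance explained is the
squared Pearson correlation between a marker's numeric coding and the trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LdResult", "ld_r", "ld_bin", "variance_explained", "factor_model_r2", "compare_ve"]


@dataclass(frozen=True)
class LdResult:
    r: float
    r2: float
    n_strains: int
    transformed: bool


def ld_r(marker_a: np.ndarray, marker_b: np.ndarray, transformed: bool = False) -> LdResult | None:
    """Signed LD between two biallelic (0/1 per strain) markers.

    Heterozygous strains must already be excluded; strains missing at either
    marker are dropped.  Returns None when a marker is monomorphic in the
    intersection (LD undefined).
    """
    a = np.asarray(marker_a, dtype=float)
    b = np.asarray(marker_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    n = a.size
    if n == 0:
        return None
    pA = float(np.mean(a == 0))
    pB = float(np.mean(b == 0))
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None
    pAB = float(np.mean((a == 0) & (b == 0)))
    D = pAB - pA * pB
    r = -D / np.sqrt(pA * (1 - pA) * pB * (1 - pB))
    return LdResult(r=float(r), r2=float(r * r), n_strains=n, transformed=transformed)


def ld_bin(r2: float, edges: tuple[float, float] = (0.3, 0.7)) -> str:
    """Assign an r2 to the low / moderate / high LD bin (edges 0.3, 0.7)."""
    lo, hi = edges
    if r2 >= hi:
        return "high"
    if r2 >= lo:
        return "moderate"
    return "low"


def variance_explained(codes: np.ndarray, values: np.ndarray) -> float | None:
    """Squared Pearson correlation between numeric marker codes and a trait.

    Codes are used untransformed (genotype indices, lengths, or SNV dosage).
    Returns None when either side is constant on the complete cases.
    """
    x = np.asarray(codes, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def factor_model_r2(codes: np.ndarray, values: np.ndarray) -> float | None:
    """R2 of the full factorial model, 1 - RSS_full / RSS_total.

    Secondary effect-size column: for a multiallelic STR with opposing
    allele effects the numeric-coding VE can badly underestimate the signal
    this captures.
    """
    x = np.asarray(codes, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(y) == 0:
        return None
    _, inv = np.unique(x, return_inverse=True)
    means = np.bincount(inv, weights=y) / np.bincount(inv)
    rss_full = float(np.sum((y - means[inv]) ** 2))
    rss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - rss_full / rss_tot


def compare_ve(
    pairs: pd.DataFrame,
    expr_values: pd.DataFrame,
    estr_codes: pd.DataFrame,
    other_codes: pd.DataFrame,
    estr_binary: pd.DataFrame,
    other_binary: pd.DataFrame,
    edges: tuple[float, float] = (0.3, 0.7),
) -> tuple[pd.DataFrame, dict]:
    """VE / LD table for (transcript, top eSTR, eQTL-or-TopSNV) pairs.

    Parameters
    ----------
    pairs : DataFrame with columns ``transcript``, ``estr_locus``,
        ``other_marker``.
    expr_values : transcripts x strains expression.
    estr_codes, other_codes : untransformed numeric codes per marker
        (rows = marker ids, columns = strains).
    estr_binary, other_binary : 0/1 codings used for LD.

    Returns the per-pair table and a summary dict (counts per LD bin, and
    the count/percentage of pairs where the eSTR explains more variance).
    """
    rows = []
    for _, pr in pairs.iterrows():
        tr, lc, om = pr["transcript"], pr["estr_locus"], pr["other_marker"]
        y = expr_values.loc[tr].to_numpy(dtype=float)
        ve_estr = variance_explained(estr_codes.loc[lc].to_numpy(dtype=float), y)
        ve_other = variance_explained(other_codes.loc[om].to_numpy(dtype=float), y)
        ld = ld_r(
            estr_binary.loc[lc].to_numpy(dtype=float),
            other_binary.loc[om].to_numpy(dtype=float),
            transformed=True,
        )
        xs = estr_codes.loc[lc]
        rows.append(
            {
                "transcript": tr,
                "estr_locus": lc,
                "other_marker": om,
                "ve_estr": ve_estr,
                "ve_other": ve_other,
                "ve_estr_factor": factor_model_r2(xs.to_numpy(dtype=float), y),
                "n_alleles_estr": int(xs.dropna().nunique()),
                "r2": ld.r2 if ld else np.nan,
                "ld_bin": ld_bin(ld.r2, edges) if ld else "undefined",
            }
        )
    table = pd.DataFrame(rows)
    summary: dict = {"n_pairs": len(table)}
    if len(table):
        scored = table.dropna(subset=["ve_estr", "ve_other"])
        n_gt = int((scored["ve_estr"] > scored["ve_other"]).sum())
        summary["n_estr_gt_other"] = n_gt
        summary["pct_estr_gt_other"] = round(100.0 * n_gt / len(scored)) if len(scored) else None
        summary["ld_bin_counts"] = table["ld_bin"].value_counts().to_dict()
    return table, summary
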