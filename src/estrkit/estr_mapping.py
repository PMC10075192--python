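"""eSTR discovery: windowed candidates, factorial LRT, permutation nulls,
Bonferroni calling, hotspot common-eSTR detection, motif enrichment.

The association test compares the nested ordinary-least-squares models

    full:    expression ~ STR code (factorial)
    reduced: expression ~ 1

under a Gaussian likelihood; the statistic is ``n * ln(RSS_red / RSS_full)``,
referred to a chi-square with ``levels - 1`` degrees of freedom.  Each real
test is accompanied by tests on codes shuffled across the retained strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, IntervalSet, TransformedStrMatrix
from .io_core import RunConfig
from .str_prep import filter_common

__all__ = [
    "AssociationResult",
    "lrt_association",
    "permuted_association",
    "bonferroni_threshold",
    "select_local_candidates",
    "select_distant_candidates",
    "map_local",
    "map_distant",
    "call_estrs",
    "find_common_estrs",
    "motif_enrichment",
]

# statistic reported when the full model fits exactly (RSS_full = 0)
LRT_STAT_CAP = 1e6
P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class AssociationResult:
    transcript: str
    locus: str
    coding_kind: str
    n_strains: int
    n_codes: int
    lrt_stat: float
    df: int
    p_value: float
    is_permuted: bool
    distance_to_tss: float


def lrt_association(expression: np.ndarray, codes: np.ndarray) -> tuple[float, int, float, int, int]:
    """Gaussian likelihood-ratio test of a factorial one-way model vs the mean.

    Returns ``(stat, df, p, n, k)`` where ``k`` is the number of factor
    levels with at least one observation.  Strains with a missing value in
    either vector are excluded before fitting, so empty levels never enter.
    """
    y = np.asarray(expression, dtype=float)
    c = np.asarray(codes, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(c))
    y, c = y[ok], c[ok]
    n = y.size
    levels, inv = np.unique(c, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("need >= 2 factor levels after dropping missing")
    if n <= k + 1:
        raise ValueError(f"too few strains (n={n}) for {k} levels")
    rss_red = float(np.sum((y - y.mean()) ** 2))
    group_means = np.bincount(inv, weights=y) / np.bincount(inv)
    rss_full = float(np.sum((y - group_means[inv]) ** 2))
    df = k - 1
    if rss_red <= 0.0:
        return 0.0, df, 1.0, n, k
    if rss_full <= 1e-12 * rss_red:
        return LRT_STAT_CAP, df, P_FLOOR, n, k
    stat = n * np.log(rss_red / rss_full)
    p = float(stats.chi2.sf(stat, df))
    return float(stat), df, max(p, P_FLOOR), n, k


def permuted_association(
    expression: np.ndarray, codes: np.ndarray, rng: np.random.Generator
) -> tuple[float, int, float, int, int]:
    """LRT after shuffling the codes uniformly across the retained strains."""
    y = np.asarray(expression, dtype=float)
    c = np.asarray(codes, dtype=float).copy()
    ok = ~(np.isnan(y) | np.isnan(c))
    c[ok] = rng.permutation(c[ok])
    return lrt_association(y, c)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Candidate selection


def _signed_distance(loci: pd.DataFrame, tss: int, strand: str) -> np.ndarray:
    mid = (loci["pos"].to_numpy() + loci["end"].to_numpy()) / 2.0
    d = mid - tss
    return -d if strand == "-" else d


def select_local_candidates(
    transcript: str,
    meta: pd.DataFrame,
    loci: pd.DataFrame,
    window_bp: int,
) -> pd.DataFrame:
    """STR loci whose interval overlaps +/- window_bp around the transcript's
    TSS (closed boundary), on the same chromosome, with signed TSS distance
    (upstream negative with respect to strand)."""
    if transcript not in meta.index:
        raise KeyError(f"transcript {transcript!r} has no coordinates")
    row = meta.loc[transcript]
    tss, chrom, strand = int(row["tss"]), row["chrom"], row["strand"]
    lo, hi = tss - window_bp, tss + window_bp
    sel = loci[(loci["chrom"] == chrom) & (loci["end"] >= lo) & (loci["pos"] <= hi)].copy()
    sel["distance_to_tss"] = _signed_distance(sel, tss, strand)
    return sel


def select_distant_candidates(
    transcript: str,
    meta: pd.DataFrame,
    eqtl: pd.DataFrame,
    loci: pd.DataFrame,
    window_bp: int,
) -> pd.DataFrame:
    """Union over the transcript's distant-eQTL regions, each widened by
    +/- window_bp, intersected with the STR loci (deduplicated)."""
    regions = eqtl[(eqtl["transcript"] == transcript) & (eqtl["klass"] == "distant")]
    keep = np.zeros(len(loci), dtype=bool)
    pos, end, chrom = loci["pos"].to_numpy(), loci["end"].to_numpy(), loci["chrom"].to_numpy()
    for _, r in regions.iterrows():
        lo, hi = int(r["start"]) - window_bp, int(r["end"]) + window_bp
        keep |= (chrom == r["chrom"]) & (end >= lo) & (pos <= hi)
    sel = loci[keep].copy()
    row = meta.loc[transcript]
    sel["distance_to_tss"] = _signed_distance(sel, int(row["tss"]), row["strand"])
    return sel


# ---------------------------------------------------------------------------
# Mapping drivers


def _test_one(
    transcript: str,
    locus: str,
    y: np.ndarray,
    codes: np.ndarray,
    coding_kind: str,
    distance: float,
    min_freq: float,
    n_perm: int,
    rng: np.random.Generator,
) -> list[AssociationResult]:
    complete = ~(np.isnan(y) | np.isnan(codes))
    masked = np.where(complete, codes, np.nan)
    filt = filter_common(masked, min_freq)
    if filt is None:
        return []
    keep, _ = filt
    yk, ck = y[keep], codes[keep]
    k = np.unique(ck).size
    if yk.size <= k + 1:
        return []
    out = []
    stat, df, p, n, k = lrt_association(yk, ck)
    out.append(
        AssociationResult(transcript, locus, coding_kind, n, k, stat, df, p, False, distance)
    )
    for _ in range(n_perm):
        stat, df, p, n, k = permuted_association(yk, ck, rng)
        out.append(
            AssociationResult(transcript, locus, coding_kind, n, k, stat, df, p, True, distance)
        )
    return out


def _results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    cols = [
        "transcript", "locus", "coding_kind", "n_strains", "n_codes",
        "lrt_stat", "df", "p_value", "is_permuted", "distance_to_tss",
    ]
    return pd.DataFrame([r.__dict__ for r in results], columns=cols)


def _run_family(
    expr: ExpressionMatrix,
    codes: TransformedStrMatrix,
    config: RunConfig,
    candidate_fn,
    transcripts: list[str] | None,
    mask: IntervalSet | None,
    seed_offset: int,
) -> pd.DataFrame:
    strains = [s for s in expr.strains if s in set(codes.strains)]
    values = expr.values[strains]
    cmat = codes.codes[strains]
    loci = codes.provenance.loci if codes.provenance is not None else None
    if loci is None:
        raise ValueError("transformed matrix lacks locus coordinates (provenance)")
    if mask is not None and len(mask):
        hit = mask.covers(
            loci["chrom"].to_numpy(), loci["pos"].to_numpy(), loci["end"].to_numpy()
        )
        loci = loci[~hit]
    rng = np.random.default_rng(config.rng_seed + seed_offset)
    results: list[AssociationResult] = []
    for transcript in transcripts if transcripts is not None else expr.transcripts:
        cands = candidate_fn(transcript, loci)
        if cands.empty:
            continue
        y = values.loc[transcript].to_numpy(dtype=float)
        for locus, dist in zip(cands.index, cands["distance_to_tss"]):
            results.extend(
                _test_one(
                    transcript,
                    locus,
                    y,
                    cmat.loc[locus].to_numpy(dtype=float),
                    codes.coding_kind,
                    float(dist),
                    config.common_allele_freq,
                    config.n_permutations_per_test,
                    rng,
                )
            )
    return _results_frame(results)


def map_local(
    expr: ExpressionMatrix,
    codes: TransformedStrMatrix,
    config: RunConfig,
    transcripts: list[str] | None = None,
    divergent_mask: IntervalSet | None = None,
) -> pd.DataFrame:
    """All local tests (real + permuted) for one coding, one row per test."""
    def cand(tr, loci):
        return select_local_candidates(tr, expr.meta, loci, config.local_window_bp)
    return _run_family(expr, codes, config, cand, transcripts, divergent_mask, seed_offset=101)


def map_distant(
    expr: ExpressionMatrix,
    codes: TransformedStrMatrix,
    eqtl: pd.DataFrame,
    config: RunConfig,
    transcripts: list[str] | None = None,
    divergent_mask: IntervalSet | None = None,
) -> pd.DataFrame:
    """Distant tests: candidates come from the transcript's distant-eQTL
    regions widened by the distant window."""
    with_distant = set(eqtl.loc[eqtl["klass"] == "distant", "transcript"])
    todo = [t for t in (transcripts or expr.transcripts) if t in with_distant]
    def cand(tr, loci):
        return select_distant_candidates(tr, expr.meta, eqtl, loci, config.distant_window_bp)
    return _run_family(expr, codes, config, cand, todo, divergent_mask, seed_offset=202)


# ---------------------------------------------------------------------------
# Calling


def call_estrs(results: pd.DataFrame, klass: str, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni calling over one (class, coding) family of real tests.

    The family size is the number of real tests actually run.  Per
    transcript, the minimum-p passing call is flagged top; ties break to the
    smaller absolute TSS distance, then lexicographic locus id.
    """
    real = results[~results["is_permuted"]].copy()
    if real.empty:
        return real.assign(klass=klass, passes_bonferroni=False, is_top_for_transcript=False)
    threshold = bonferroni_threshold(len(real), alpha)
    real["klass"] = klass
    real["passes_bonferroni"] = real["p_value"] <= threshold
    real["is_top_for_transcript"] = False
    passing = real[real["passes_bonferroni"]]
    if not passing.empty:
        ranked = passing.assign(absdist=passing["distance_to_tss"].abs()).sort_values(
            ["transcript", "p_value", "absdist", "locus"]
        )
        top_idx = ranked.groupby("transcript", sort=False).head(1).index
        real.loc[top_idx, "is_top_for_transcript"] = True
    real.attrs["bonferroni_threshold"] = threshold
    real.attrs["n_tests"] = len(real)
    return real


def merge_coding_calls(genotype_calls: pd.DataFrame, length_calls: pd.DataFrame) -> pd.DataFrame:
    """Union of Bonferroni-passing calls from the two codings.

    The genotype and length families are tested and thresholded
    independently; this report flags each (transcript, locus) pair with the
    coding(s) that found it: 'genotype', 'length' or 'both'.
    """
    key = ["transcript", "locus"]
    g = genotype_calls.loc[genotype_calls.get("passes_bonferroni", False), key]
    l = length_calls.loc[length_calls.get("passes_bonferroni", False), key]
    merged = pd.merge(g.assign(_g=True), l.assign(_l=True), on=key, how="outer")
    merged["found_by"] = np.select(
        [merged["_g"].notna() & merged["_l"].notna(), merged["_g"].notna()],
        ["both", "genotype"], default="length",
    )
    return merged[key + ["found_by"]].sort_values(key).reset_index(drop=True)


def find_common_estrs(
    distant_calls: pd.DataFrame,
    hotspots: IntervalSet,
    eqtl: pd.DataFrame,
    loci: pd.DataFrame,
    window_bp: int = 1_000_000,
    min_eqtl: int = 5,
) -> pd.DataFrame:
    """Per-hotspot eSTRs associated with >= ``min_eqtl`` of the hotspot's
    distant eQTL.

    An eSTR is linked to an eQTL when the eSTR passes Bonferroni for the
    eQTL's transcript and sits within hotspot +/- window_bp.
    """
    passing = distant_calls[distant_calls["passes_bonferroni"]]
    deqtl = eqtl[eqtl["klass"] == "distant"]
    rows = []
    for h, hs in hotspots.df.iterrows():
        in_hot = deqtl[
            (deqtl["chrom"] == hs["chrom"])
            & (deqtl["peak"] >= hs["start"])
            & (deqtl["peak"] <= hs["end"])
        ]
        n_hot = len(in_hot)
        if n_hot == 0:
            continue
        lo, hi = hs["start"] - window_bp, hs["end"] + window_bp
        near = loci[(loci["chrom"] == hs["chrom"]) & (loci["end"] >= lo) & (loci["pos"] <= hi)]
        cand = passing[passing["locus"].isin(near.index)]
        for locus, grp in cand.groupby("locus"):
            linked = in_hot[in_hot["transcript"].isin(grp["transcript"])]
            n_link = linked["eqtl_id"].nunique()
            rows.append(
                {
                    "hotspot": hs["name"] or f"{hs['chrom']}:{hs['start']}-{hs['end']}",
                    "locus": locus,
                    "n_eqtl_linked": n_link,
                    "n_eqtl_in_hotspot": n_hot,
                    "fraction": n_link / n_hot,
                    "is_common": n_link >= min_eqtl,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["hotspot", "locus", "n_eqtl_linked", "n_eqtl_in_hotspot", "fraction", "is_common"],
    )


def motif_enrichment(
    called_loci: list[str], candidate_loci: list[str], loci: pd.DataFrame
) -> pd.DataFrame:
    """One-sided Fisher enrichment of each motif among called loci,
    Bonferroni-adjusted across motifs."""
    called = set(called_loci)
    cand = pd.Index(candidate_loci).unique()
    motifs = loci.loc[cand, "motif"]
    rows = []
    uniq = sorted(motifs.unique())
    for motif in uniq:
        has = motifs == motif
        is_called = motifs.index.isin(called)
        a = int((has & is_called).sum())
        b = int((~has & is_called).sum())
        c = int((has & ~is_called).sum())
        d = int((~has & ~is_called).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"motif": motif, "n_called": a, "n_candidate": a + c, "p_value": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = np.minimum(out["p_value"] * len(out), 1.0)
    return out
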