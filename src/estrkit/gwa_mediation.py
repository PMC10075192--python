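"""Mixed-model GWA of the STR-variation trait, thresholds, QTL regions,
and expression-mediation analysis.

GWA uses the standard MLMA approximation: variance components are estimated
once per kinship by REML (one spectral decomposition per chromosome in LOCO
mode), then each marker gets a generalized-least-squares Wald test with the
components held fixed.  LOCO builds the kinship from all chromosomes except
the tested one; INBRED uses a whole-genome inbred-scaled kinship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MarkerMatrix
from .heritability import build_grm, grm_eig, reml_h2

__all__ = [
    "run_gwa",
    "eigen_threshold",
    "bf_threshold",
    "define_qtl_regions",
    "MediationResult",
    "mediation_test",
    "summarize_mediation",
    "regress_out",
]


def _mlma_scan(
    y: np.ndarray,
    markers: pd.DataFrame,
    meta: pd.DataFrame,
    eig: tuple[np.ndarray, np.ndarray],
    mode: str,
) -> pd.DataFrame:
    lam, u = eig
    fit = reml_h2(y, eig=eig)
    ratio = fit.vg / fit.ve if (fit.converged and fit.ve > 0) else 0.0
    w = ratio * lam + 1.0
    v = 1.0 / w
    yt = u.T @ y
    x0 = u.T @ np.ones_like(y)
    xm = markers.to_numpy(dtype=float)
    keep = xm.std(axis=1) > 0
    xm = xm[keep]
    meta = meta[keep]
    x1 = u.T @ xm.T  # n x m
    a00 = float(np.sum(v * x0 * x0))
    a01 = (v * x0) @ x1
    a11 = np.sum(v[:, None] * x1 * x1, axis=0)
    b0 = float(np.sum(v * x0 * yt))
    b1 = (v * yt) @ x1
    det = a00 * a11 - a01 * a01
    beta = (a00 * b1 - a01 * b0) / det
    sigma_e2 = fit.ve if fit.converged else np.var(y, ddof=1)
    se = np.sqrt(sigma_e2 * a00 / det)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.maximum(p, np.nextafter(0.0, 1.0))
    return pd.DataFrame(
        {
            "marker": markers.index[keep],
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "neg_log10_p": -np.log10(p),
            "mode": mode,
        }
    )


def run_gwa(trait: pd.Series, matrix: MarkerMatrix, mode: str = "loco") -> pd.DataFrame:
    """Mixed-model association of a trait against every marker.

    ``mode='loco'``: kinship from all chromosomes except the tested one.
    ``mode='inbred'``: single whole-genome kinship with inbred scaling.
    Monomorphic markers are dropped.
    """
    strains = [s for s in matrix.strains if s in trait.index]
    y = trait.loc[strains].to_numpy(dtype=float)
    codes = matrix.codes[strains]
    meta = matrix.meta
    if mode == "inbred":
        eig = grm_eig(build_grm(codes, inbred=True))
        return _mlma_scan(y, codes, meta, eig, mode).reset_index(drop=True)
    if mode != "loco":
        raise ValueError(f"unknown GWA mode {mode!r}")
    out = []
    for chrom in meta["chrom"].unique():
        on = meta["chrom"] == chrom
        if (~on).sum() == 0:
            raise ValueError(f"LOCO: no off-chromosome markers for {chrom}")
        eig = grm_eig(build_grm(codes[~on.to_numpy()]))
        out.append(_mlma_scan(y, codes[on.to_numpy()], meta[on], eig, mode))
    return pd.concat(out, ignore_index=True)


def eigen_threshold(matrix: MarkerMatrix | pd.DataFrame, alpha: float = 0.05) -> float:
    """-log10(alpha / N_test) with N_test the Li & Ji effective number of
    independent tests from the eigenvalues of the marker correlation matrix.

    Eigenvalues are taken from the strains-by-strains Gram matrix of
    standardized genotypes (same nonzero spectrum, far cheaper than the
    markers-by-markers correlation matrix).
    """
    codes = matrix.codes if isinstance(matrix, MarkerMatrix) else matrix
    x = codes.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 strains")
    sd = x.std(axis=1)
    x = x[sd > 0]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[sd > 0][:, None]
    n = x.shape[1]
    gram = z.T @ z / n
    lam = np.clip(np.linalg.eigvalsh(gram), 0.0, None)
    # snap eigenvalues that are integral up to numerical error, so exactly
    # redundant marker blocks contribute integer counts
    near = np.abs(lam - np.round(lam)) < 1e-9
    lam = np.where(near, np.round(lam), lam)
    n_test = float(np.sum(np.where(lam >= 1.0, 1.0, 0.0) + (lam - np.floor(lam))))
    n_test = max(n_test, 1.0)
    return float(-np.log10(alpha / n_test))


def bf_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """-log10(alpha / n) over all tested markers."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return float(-np.log10(alpha / n_markers))


def define_qtl_regions(
    gwa: pd.DataFrame,
    threshold: float,
    merge_bp: int = 1_000,
    flank_markers: int = 150,
) -> pd.DataFrame:
    """QTL regions from markers above the threshold.

    Passing markers within ``merge_bp`` of one another form a cluster; each
    cluster is extended by ``flank_markers`` positions on the tested marker
    map (truncated at chromosome ends); overlapping extended regions merge.
    Output is invariant to the input row order.
    """
    regions = []
    for chrom, sub in gwa.groupby("chrom", sort=False):
        sub = sub.sort_values("pos").reset_index(drop=True)
        passing = sub.index[sub["neg_log10_p"] > threshold].to_numpy()
        if passing.size == 0:
            continue
        clusters: list[list[int]] = [[passing[0]]]
        for i in passing[1:]:
            if sub.loc[i, "pos"] - sub.loc[clusters[-1][-1], "pos"] <= merge_bp:
                clusters[-1].append(i)
            else:
                clusters.append([i])
        for cl in clusters:
            lo = max(cl[0] - flank_markers, 0)
            hi = min(cl[-1] + flank_markers, len(sub) - 1)
            peak = sub.loc[cl].sort_values(["neg_log10_p", "pos"], ascending=[False, True]).iloc[0]
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(sub.loc[lo, "pos"]),
                    "end": int(sub.loc[hi, "pos"]),
                    "peak_marker": peak["marker"],
                    "peak_pos": int(peak["pos"]),
                    "peak_neg_log10_p": float(peak["neg_log10_p"]),
                    "n_markers_above_bf": len(cl),
                }
            )
    merged: list[dict] = []
    for reg in sorted(regions, key=lambda r: (str(r["chrom"]), r["start"])):
        if merged and merged[-1]["chrom"] == reg["chrom"] and reg["start"] <= merged[-1]["end"]:
            prev = merged[-1]
            prev["end"] = max(prev["end"], reg["end"])
            prev["n_markers_above_bf"] += reg["n_markers_above_bf"]
            if reg["peak_neg_log10_p"] > prev["peak_neg_log10_p"]:
                for key in ("peak_marker", "peak_pos", "peak_neg_log10_p"):
                    prev[key] = reg[key]
        else:
            merged.append(dict(reg))
    return pd.DataFrame(
        merged,
        columns=[
            "chrom", "start", "end", "peak_marker", "peak_pos",
            "peak_neg_log10_p", "n_markers_above_bf",
        ],
    )


# ---------------------------------------------------------------------------
# Mediation


@dataclass
class MediationResult:
    qtl: str
    mediator: str
    estimate: float  # product of coefficients a*b
    total_effect: float
    direct_effect: float
    p_raw: float
    note: str = ""


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def _ab(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(a*b, total, direct) from the two-regression linear mediation model."""
    a = _ols_slope(x, m)
    X = np.column_stack([np.ones_like(x), x, m])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    direct, b = float(coef[1]), float(coef[2])
    total = _ols_slope(x, y)
    return a * b, total, direct


def mediation_test(
    exposure: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    seed: int = 0,
    n_boot: int = 1000,
    qtl: str = "qtl",
    mediator_id: str = "mediator",
) -> MediationResult:
    """Linear mediation: fit M = a X, Y = c' X + b M; the mediated effect is
    a*b with a nonparametric strain-resampling bootstrap p-value."""
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(m) | np.isnan(y))
    x, m, y = x[ok], m[ok], y[ok]
    if np.ptp(x) == 0:
        raise ValueError("exposure has no variance")
    if np.ptp(m) == 0:
        return MediationResult(qtl, mediator_id, np.nan, np.nan, np.nan, np.nan,
                               note="constant mediator")
    ab, total, direct = _ab(x, m, y)
    rng = np.random.default_rng(seed)
    n = x.size
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        xi = x[idx]
        if np.ptp(xi) == 0 or np.ptp(m[idx]) == 0:
            boots[i] = 0.0
            continue
        boots[i], _, _ = _ab(xi, m[idx], y[idx])
    p = 2.0 * min((boots <= 0).mean(), (boots >= 0).mean())
    p = float(min(max(p, 1.0 / n_boot), 1.0))
    return MediationResult(qtl, mediator_id, float(ab), float(total), float(direct), p)


def summarize_mediation(results: list[MediationResult], alpha: float = 0.05,
                        percentile: float = 99.0) -> pd.DataFrame:
    """BH-adjust the family and flag significant mediators.

    A mediator passes when adjusted p < alpha, its estimate exceeds the
    given percentile of all estimates, and the estimate is interpretable:
    proportion mediated a*b / total in [0, 1.2] (the upper tolerance keeps
    full mediation, where sampling noise pushes the ratio slightly past 1,
    from being discarded).
    """
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        return df
    valid = df["p_raw"].notna()
    df["p_adjusted"] = np.nan
    if valid.any():
        df.loc[valid, "p_adjusted"] = multipletests(df.loc[valid, "p_raw"], method="fdr_bh")[1]
    cut = np.nanpercentile(df["estimate"], percentile)
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = df["estimate"] / df["total_effect"]
    df["proportion_mediated"] = prop
    df["interpretable"] = ((prop >= 0.0) & (prop <= 1.2)).fillna(False)
    df["passes"] = (
        (df["p_adjusted"] < alpha) & (df["estimate"] > cut) & df["interpretable"]
    ).fillna(False)
    return df


def regress_out(trait: pd.Series, expression: pd.Series) -> pd.Series:
    """Residualize the trait on a mediator's expression (OLS), re-centered.

    Used to ask whether a QTL acts through the mediator: a fully mediated
    QTL loses significance on the residual trait, a direct one keeps it.
    """
    common = trait.index.intersection(expression.index)
    y = trait.loc[common].to_numpy(dtype=float)
    x = expression.loc[common].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if np.ptp(x[ok]) == 0:
        raise ValueError("mediator expression is constant")
    slope = _ols_slope(x[ok], y[ok])
    resid = np.full(y.shape, np.nan)
    resid[ok] = y[ok] - y[ok].mean() - slope * (x[ok] - x[ok].mean())
    resid[ok] -= resid[ok].mean()
    return pd.Series(resid, index=common, name=f"{trait.name}_resid")
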