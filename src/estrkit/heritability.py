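"""Marker preparation, genomic relationship matrices and REML heritability.

The mixed model is y = mu + g + e with g ~ N(0, s2_g G) and e ~ N(0, s2_e I).
REML is solved by one spectral decomposition of G followed by a 1-D profile
optimization of the variance ratio lambda = s2_g / s2_e — exact for this
single-kinship model class.  h2 = s2_g / (s2_g + s2_e), with G normalized to
unit mean diagonal so the ratio is on the phenotypic scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import MarkerMatrix, TransformedStrMatrix
from .str_prep import filter_common

logger = logging.getLogger("estrkit")

__all__ = [
    "H2Result",
    "prepare_snv_matrix",
    "prune_ld",
    "combine_snv_str",
    "build_grm",
    "grm_eig",
    "reml_h2",
    "h2_gain",
]


@dataclass(frozen=True)
class H2Result:
    trait: str
    h2: float
    vg: float
    ve: float
    matrix_kind: str
    converged: bool
    note: str = ""


# ---------------------------------------------------------------------------
# Marker preparation


def prepare_snv_matrix(
    codes: pd.DataFrame,
    meta: pd.DataFrame,
    maf_min: float = 0.05,
    prune_window: int = 50,
    prune_step: int = 10,
    prune_r2: float = 0.8,
) -> MarkerMatrix:
    """Homozygous-biallelic SNV matrix: drop any-missing/het markers, keep
    MAF >= maf_min, then greedy sliding-window LD pruning."""
    vals = codes.to_numpy(dtype=float)
    clean = ~(np.isnan(vals).any(axis=1) | ((vals != 0) & (vals != 1)).any(axis=1))
    n_dropped = int((~clean).sum())
    if n_dropped:
        logger.info("dropped %d SNVs with missing or heterozygous calls", n_dropped)
    codes = codes[clean]
    p = codes.mean(axis=1)
    maf = np.minimum(p, 1 - p)
    codes = codes[maf >= maf_min]
    meta = meta.loc[codes.index]
    keep = prune_ld(codes, meta, prune_window, prune_step, prune_r2)
    mm_meta = meta.loc[keep].copy()
    mm_meta["source"] = "snv"
    return MarkerMatrix(codes=codes.loc[keep].astype(float), meta=mm_meta)


def prune_ld(
    codes: pd.DataFrame,
    meta: pd.DataFrame,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.8,
) -> pd.Index:
    """PLINK-style greedy ``indep-pairwise`` pruning; returns surviving ids.

    Per chromosome, on position-sorted markers: in each window of ``window``
    markers (advanced by ``step``), while any surviving pair has r2 >=
    ``r2_max``, drop the member with the lower minor-allele frequency (tie:
    the later position).  Fully deterministic.
    """
    survivors: list = []
    for chrom in meta["chrom"].unique():
        ids = meta[meta["chrom"] == chrom].sort_values("pos").index
        x = codes.loc[ids].to_numpy(dtype=float)
        p = x.mean(axis=1)
        maf = np.minimum(p, 1 - p)
        m = len(ids)
        alive = np.ones(m, dtype=bool)
        for start in range(0, max(m - 1, 1), step):
            idx = [i for i in range(start, min(start + window, m)) if alive[i]]
            changed = True
            while changed and len(idx) > 1:
                changed = False
                for a_i in range(len(idx)):
                    for b_i in range(a_i + 1, len(idx)):
                        i, j = idx[a_i], idx[b_i]
                        r = np.corrcoef(x[i], x[j])[0, 1]
                        if np.isnan(r) or r * r < r2_max:
                            continue
                        if maf[i] < maf[j]:
                            drop = i
                        elif maf[j] < maf[i]:
                            drop = j
                        else:
                            drop = max(i, j)  # tie: later position
                        alive[drop] = False
                        idx.remove(drop)
                        changed = True
                        break
                    if changed:
                        break
        survivors.extend(ids[alive])
    return pd.Index(survivors)


def combine_snv_str(
    snv: MarkerMatrix,
    str_codes: TransformedStrMatrix,
    str_loci: pd.DataFrame,
    min_freq: float = 0.05,
) -> MarkerMatrix:
    """Concatenate the SNV matrix with imputed STR genotype codes.

    STR loci must be complete (imputed) and are kept only with at least two
    common codes (frequency > min_freq); codes enter as plain integers,
    standardized like SNVs at GRM time.
    """
    strains = [s for s in snv.strains if s in set(str_codes.strains)]
    keep_loci = [
        locus
        for locus in str_codes.codes.index
        if filter_common(str_codes.codes.loc[locus, strains], min_freq) is not None
    ]
    str_part = str_codes.codes.loc[keep_loci, strains]
    str_meta = str_loci.loc[keep_loci, ["chrom", "pos"]].copy()
    str_meta["source"] = "str"
    codes = pd.concat([snv.codes[strains], str_part])
    meta = pd.concat([snv.meta[["chrom", "pos", "source"]], str_meta])
    return MarkerMatrix(codes=codes, meta=meta)


# ---------------------------------------------------------------------------
# GRM and REML


def build_grm(matrix: MarkerMatrix | pd.DataFrame, inbred: bool = False) -> pd.DataFrame:
    """Standardized-genotype GRM, G = Z'Z / M.

    Each marker is centered and scaled by its observed (population) SD, so
    diagonals average 1.  With ``inbred=True`` the 0/2-equivalent scaling is
    used (effective allele coding doubled, expected binomial variance): for
    homozygous panels this multiplies G by 2, putting diagonals near
    1 + F = 2.  Zero-variance markers are dropped with a log entry.
    """
    codes = matrix.codes if isinstance(matrix, MarkerMatrix) else matrix
    x = codes.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("dropped %d zero-variance markers from GRM", int((~keep).sum()))
    x, sd = x[keep], sd[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    g = z.T @ z / z.shape[0]
    if inbred:
        g = 2.0 * g
    return pd.DataFrame(g, index=codes.columns, columns=codes.columns)


def grm_eig(grm: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a (mean-diagonal-normalized) GRM."""
    g = np.asarray(grm, dtype=float)
    g = g / np.mean(np.diag(g))
    lam, u = np.linalg.eigh(g)
    return np.clip(lam, 0.0, None), u


def _reml_neg_ll(log_lam: float, lam: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    ratio = 10.0 ** log_lam
    w = ratio * lam + 1.0
    sxx = np.sum(xt * xt / w)
    beta = np.sum(xt * yt / w) / sxx
    resid = yt - beta * xt
    rss = np.sum(resid * resid / w)
    n = yt.size
    sigma_e2 = rss / (n - 1)
    ll = -0.5 * ((n - 1) * np.log(sigma_e2) + np.sum(np.log(w)) + np.log(sxx))
    return -ll


def reml_h2(
    trait: pd.Series | np.ndarray,
    grm: pd.DataFrame | np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    trait_id: str = "trait",
    matrix_kind: str = "snv",
) -> H2Result:
    """REML narrow-sense heritability from a single GRM.

    Either ``grm`` or its precomputed ``eig`` (from :func:`grm_eig`) must be
    given; passing ``eig`` lets many traits share one decomposition.
    """
    if eig is None:
        if grm is None:
            raise ValueError("provide grm or eig")
        eig = grm_eig(grm)
    lam, u = eig
    y = np.asarray(trait, dtype=float)
    if np.isnan(y).any():
        raise ValueError("trait contains missing values; complete cases required")
    if lam.max() - lam.min() < 1e-8 * max(1.0, lam.max()):
        return H2Result(trait_id, np.nan, np.nan, np.nan, matrix_kind, False,
                        "GRM proportional to identity: h2 unidentifiable")
    yt = u.T @ y
    xt = u.T @ np.ones_like(y)
    grid = np.linspace(-3.0, 3.0, 61)
    vals = [_reml_neg_ll(g, lam, yt, xt) for g in grid]
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    opt = optimize.minimize_scalar(
        _reml_neg_ll, bounds=(lo, hi), args=(lam, yt, xt), method="bounded",
        options={"xatol": 1e-6},
    )
    ratio = 10.0 ** float(opt.x)
    w = ratio * lam + 1.0
    sxx = np.sum(xt * xt / w)
    beta = np.sum(xt * yt / w) / sxx
    rss = np.sum((yt - beta * xt) ** 2 / w)
    sigma_e2 = rss / (y.size - 1)
    vg, ve = ratio * sigma_e2, sigma_e2
    h2 = float(np.clip(vg / (vg + ve), 0.0, 1.0))
    if best == 0:  # ratio pinned at the lower search bound: no genetic variance
        h2, vg = 0.0, 0.0
    return H2Result(trait_id, h2, float(vg), float(ve), matrix_kind, bool(opt.success))


def h2_gain(
    trait: pd.Series | np.ndarray,
    grm_snv: pd.DataFrame,
    grm_snv_str: pd.DataFrame,
    trait_id: str = "trait",
) -> tuple[H2Result, H2Result, bool]:
    """h2 under SNV-only vs SNV+STR kinship, plus the gain flag."""
    r_snv = reml_h2(trait, grm=grm_snv, trait_id=trait_id, matrix_kind="snv")
    r_both = reml_h2(trait, grm=grm_snv_str, trait_id=trait_id, matrix_kind="snv_str")
    return r_snv, r_both, bool(r_both.h2 > r_snv.h2)
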