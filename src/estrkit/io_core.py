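"""Readers/writers for external formats, run configuration and run logging.

No science lives here.  VCF parsing goes through :mod:`pysam`; TSV and BED
through :mod:`pandas`.  Internal coordinates are 1-based inclusive; BED
(0-based half-open) is converted on ingest and on export.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .containers import MISSING, ExpressionMatrix, IntervalSet, StrGenotypeMatrix

logger = logging.getLogger("estrkit")

__all__ = [
    "RunConfig",
    "read_str_genotypes",
    "write_str_genotypes_tsv",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_intervals",
    "write_intervals_bed",
    "read_snv_genotypes",
    "read_eqtl_records",
    "common_strains",
    "write_table",
    "log_run",
]


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants, with the study's defaults.

    ``local_window_bp``/``distant_window_bp`` are half-widths: a "2 Mb
    surrounding" window is +/- 1 Mb around the anchor, boundary closed.
    """

    alpha_family: float = 0.05
    local_window_bp: int = 1_000_000
    distant_window_bp: int = 1_000_000
    common_allele_freq: float = 0.05
    n_permutations_per_test: int = 1
    rng_seed: int = 0
    ld_bin_edges: tuple[float, float] = (0.3, 0.7)
    hotspot_min_eqtl: int = 5
    qtl_merge_bp: int = 1_000
    qtl_flank_markers: int = 150

    def __post_init__(self) -> None:
        for name in ("alpha_family", "common_allele_freq"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        for name in ("local_window_bp", "distant_window_bp", "qtl_merge_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.ld_bin_edges
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError(f"ld_bin_edges must be ordered r2 values in [0,1]")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# STR genotypes


def _parse_gt(gt: str, line_no: int) -> tuple[int, int]:
    for sep in ("|", "/"):
        if sep in gt:
            a, b = gt.split(sep, 1)
            break
    else:
        raise ValueError(f"malformed genotype string {gt!r} at line {line_no}")
    try:
        ai = MISSING if a == "." else int(a)
        bi = MISSING if b == "." else int(b)
    except ValueError as exc:
        raise ValueError(f"malformed genotype string {gt!r} at line {line_no}") from exc
    if ai == MISSING or bi == MISSING:
        return MISSING, MISSING
    return ai, bi


def read_str_genotypes(path: str | os.PathLike, dialect: str = "vcf") -> StrGenotypeMatrix:
    """Read diploid STR calls from a VCF or the package's wide TSV dialect."""
    if dialect == "vcf":
        return _read_str_vcf(path)
    if dialect == "tsv":
        return _read_str_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_str_vcf(path: str | os.PathLike) -> StrGenotypeMatrix:
    vf = pysam.VariantFile(os.fspath(path))
    strains = list(vf.header.samples)
    rows, allele_reg, a1s, a2s, passes = [], [], [], [], []
    for rec in vf:
        alleles = [rec.ref] + [a for a in (rec.alts or ())]
        site_pass = (not rec.filter.keys()) or ("PASS" in rec.filter.keys())
        locus = rec.id or f"{rec.chrom}:{rec.pos}"
        motif = rec.info.get("MOTIF", "")
        if isinstance(motif, tuple):
            motif = motif[0]
        rows.append(
            {
                "locus": locus,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "end": rec.pos + len(rec.ref) - 1,
                "motif": motif,
            }
        )
        allele_reg.append(alleles)
        r1, r2, rp = [], [], []
        for s in strains:
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or any(g is None for g in gt):
                ai = bi = MISSING
            else:
                ai, bi = int(gt[0]), int(gt[1])
                if ai >= len(alleles) or bi >= len(alleles):
                    raise ValueError(
                        f"allele index without registered allele at {locus} sample {s}"
                    )
            ft = call.get("FT")
            rp.append(site_pass if ft is None else ft == "PASS")
            r1.append(ai)
            r2.append(bi)
        a1s.append(r1)
        a2s.append(r2)
        passes.append(rp)
    loci = pd.DataFrame(rows).set_index("locus")
    return StrGenotypeMatrix(
        loci=loci,
        alleles=allele_reg,
        a1=np.array(a1s, dtype=np.int32).reshape(len(loci), len(strains)),
        a2=np.array(a2s, dtype=np.int32).reshape(len(loci), len(strains)),
        passes=np.array(passes, dtype=bool).reshape(len(loci), len(strains)),
        strains=strains,
    )


def _read_str_tsv(path: str | os.PathLike) -> StrGenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["locus", "chrom", "pos", "end", "motif", "alleles", "filter"]
    for col in fixed:
        if col not in df.columns:
            raise ValueError(f"STR TSV lacks required column {col!r}")
    strains = [c for c in df.columns if c not in fixed]
    allele_reg = [a.split(",") for a in df["alleles"]]
    n_loci, n_strains = len(df), len(strains)
    a1 = np.full((n_loci, n_strains), MISSING, dtype=np.int32)
    a2 = np.full_like(a1, MISSING)
    for j, s in enumerate(strains):
        for i, gt in enumerate(df[s]):
            a1[i, j], a2[i, j] = _parse_gt(gt, line_no=i + 2)
    passes = np.repeat((df["filter"] == "PASS").to_numpy()[:, None], n_strains, axis=1)
    loci = df[["locus", "chrom", "pos", "end", "motif"]].copy()
    loci["pos"] = loci["pos"].astype(int)
    loci["end"] = loci["end"].astype(int)
    return StrGenotypeMatrix(
        loci=loci.set_index("locus"),
        alleles=allele_reg,
        a1=a1,
        a2=a2,
        passes=passes,
        strains=strains,
    )


def write_str_genotypes_tsv(mat: StrGenotypeMatrix, path: str | os.PathLike) -> None:
    out = mat.loci.reset_index()[["locus", "chrom", "pos", "end", "motif"]].copy()
    out["alleles"] = [",".join(a) for a in mat.alleles]
    site_pass = mat.passes.all(axis=1)
    out["filter"] = np.where(site_pass, "PASS", "FAIL")
    for j, s in enumerate(mat.strains):
        col = []
        for i in range(mat.n_loci):
            ai, bi = mat.a1[i, j], mat.a2[i, j]
            col.append("./." if ai == MISSING else f"{ai}|{bi}")
        out[s] = col
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression


def read_expression_matrix(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a transcript x strain TSV with a metadata block per transcript.

    Expected columns: transcript, gene, chrom, tss, strand, then one column
    per strain.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript": str})
    meta_cols = ["transcript", "gene", "chrom", "tss", "strand"]
    for col in meta_cols:
        if col not in df.columns:
            raise ValueError(f"expression TSV lacks required column {col!r}")
    if df["transcript"].duplicated().any():
        raise ValueError("duplicate transcript id in expression TSV")
    strains = [c for c in df.columns if c not in meta_cols]
    values = df[strains].copy()
    for col in strains:
        try:
            values[col] = pd.to_numeric(values[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            row = df.loc[bad, "transcript"].iloc[0] if bad.any() else "?"
            raise ValueError(f"non-numeric expression cell at ({row}, {col})") from exc
    values.index = df["transcript"]
    meta = df[meta_cols].set_index("transcript")
    meta["tss"] = meta["tss"].astype(int)
    return ExpressionMatrix(values=values, meta=meta)


def write_expression_matrix(em: ExpressionMatrix, path: str | os.PathLike) -> None:
    out = em.meta.copy()
    out[em.values.columns] = em.values
    out.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Intervals (BED)


def read_intervals(path: str | os.PathLike) -> IntervalSet:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name"]))
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df["name"] = df[3].astype(str) if 3 in df.columns else ""
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError(f"BED start >= end at line {int(df.index[bad][0]) + 1}")
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    return IntervalSet(df[["chrom", "start", "end", "name"]])


def write_intervals_bed(ivs: IntervalSet, path: str | os.PathLike) -> None:
    out = ivs.df.copy()
    out["start"] = out["start"] - 1  # back to 0-based half-open
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# SNVs and eQTL tables


def read_snv_genotypes(path: str | os.PathLike, dialect: str = "vcf") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read biallelic SNV genotypes.

    Returns ``(codes, meta)``: codes is markers x strains with 0 (hom ref),
    1 (hom alt), 0.5 (het) or NaN (missing); meta has chrom/pos.  Downstream
    filtering (het/missing drop, MAF, pruning) lives in :mod:`heritability`.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"marker": str})
        meta = df[["marker", "chrom", "pos"]].set_index("marker")
        codes = df.drop(columns=["chrom", "pos"]).set_index("marker").astype(float)
        return codes, meta
    vf = pysam.VariantFile(os.fspath(path))
    strains = list(vf.header.samples)
    rows, data = [], []
    for rec in vf:
        rows.append(
            {"marker": rec.id or f"{rec.chrom}:{rec.pos}", "chrom": rec.chrom, "pos": rec.pos}
        )
        vals = []
        for s in strains:
            gt = rec.samples[s].get("GT")
            if gt is None or any(g is None for g in gt):
                vals.append(np.nan)
            else:
                vals.append((gt[0] + gt[1]) / 2.0)
        data.append(vals)
    meta = pd.DataFrame(rows).set_index("marker")
    codes = pd.DataFrame(data, index=meta.index, columns=strains)
    return codes, meta


def read_eqtl_records(path: str | os.PathLike) -> pd.DataFrame:
    """eQTL table: eqtl_id, transcript, chrom, peak, start, end, klass."""
    df = pd.read_csv(path, sep="\t", dtype={"eqtl_id": str, "transcript": str, "chrom": str})
    required = {"eqtl_id", "transcript", "chrom", "peak", "start", "end", "klass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"eQTL TSV lacks columns: {sorted(missing)}")
    bad = ~df["klass"].isin(["local", "distant"])
    if bad.any():
        raise ValueError(f"unknown eQTL class {df.loc[bad, 'klass'].iloc[0]!r}")
    return df


# ---------------------------------------------------------------------------
# Helpers


def common_strains(*strain_lists: list[str]) -> list[str]:
    """Intersection of strain sets, in the order of the first list.

    Dropped strains are logged: every analysis runs on strains present in all
    of its required inputs.
    """
    keep = set(strain_lists[0])
    for other in strain_lists[1:]:
        keep &= set(other)
    dropped = [s for s in strain_lists[0] if s not in keep]
    if dropped:
        logger.info("dropping %d strains absent from some input: %s", len(dropped), dropped[:10])
    return [s for s in strain_lists[0] if s in keep]


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    """TSV with fixed column order and 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _file_sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def log_run(config: RunConfig, inputs: dict[str, str | os.PathLike]) -> dict[str, str]:
    """Record config hash, seed and input checksums; returns the record."""
    record = {"config": config.digest(), "seed": str(config.rng_seed)}
    for name, path in inputs.items():
        record[name] = _file_sha256(path)
    logger.info("run: %s", record)
    return record
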