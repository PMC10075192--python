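"""Synthetic strain panels with the statistical structure the pipeline assumes.

The generator emulates a panel of inbred, selfing strains: STR loci with 1-6
bp motifs and several alleles (mostly homozygous calls, configurable
missingness), block-LD SNVs, transcripts with planted local/distant STR
effects including a mediator pathway, quantitative traits of chosen
heritability, and mutation-accumulation panels mutated at stated per-type
rates.  Every planted structure is recorded in a ground-truth ledger so
recovery can be scored.

Default desk scale mirrors the study's proportions at roughly 1/10:
200 strains, 2,000 STRs, 5,000 SNVs, 1,000 transcripts.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, ExpressionMatrix, StrGenotypeMatrix

__all__ = [
    "SimTruth",
    "simulate_str_panel",
    "simulate_snv_panel",
    "make_transcript_table",
    "simulate_expression",
    "simulate_trait",
    "simulate_ma_panel",
    "write_desk_fixture",
]

CHROMS = ("I", "II", "III", "IV", "V", "X")
CHROM_LEN = 18_000_000
BASES = "ACGT"


@dataclass
class SimTruth:
    """Ground-truth ledger for every planted structure."""

    planted_local_effects: list[dict] = field(default_factory=list)
    planted_distant_effects: list[dict] = field(default_factory=list)
    mediation_direct_effect: float = 0.0
    mutation_rates_true: tuple[float, float, float] | None = None
    realized_mutations: dict[str, int] = field(default_factory=dict)
    h2_true: float | None = None

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _random_motif(rng: np.random.Generator, length: int) -> str:
    # avoid single-base homopolymer motifs of length > 1 collapsing alleles
    while True:
        motif = "".join(rng.choice(list(BASES), size=length))
        if length == 1 or len(set(motif)) > 1:
            return motif


def simulate_str_panel(
    n_strains: int = 200,
    n_loci: int = 2000,
    allele_count_dist: dict[int, float] | None = None,
    motif_lengths: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    missing_rate: float = 0.05,
    het_rate: float = 0.01,
    seed: int = 0,
    common_locus_fraction: float = 0.8,
) -> StrGenotypeMatrix:
    """Inbred-strain STR panel.

    Allele sequences are a motif repeated a per-allele number of times (so
    length = motif length x repeats); occasionally an allele is an
    equal-length substitution variant of another, exercising the difference
    between genotype and length codings.  ``common_locus_fraction`` controls
    how many loci draw balanced allele frequencies (and thus tend to pass
    the two-common-alleles filter); the rest are dominated by one allele.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    if not (0 <= missing_rate < 1 and 0 <= het_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    if allele_count_dist is None:
        allele_count_dist = {2: 0.35, 3: 0.3, 4: 0.2, 5: 0.1, 6: 0.05}
    ks = np.array(sorted(allele_count_dist))
    pk = np.array([allele_count_dist[k] for k in ks], dtype=float)
    if (pk < 0).any() or pk.sum() <= 0 or ks.min() < 2:
        raise ValueError("allele_count_dist must be a distribution over counts >= 2")
    pk = pk / pk.sum()
    rng = np.random.default_rng(seed)
    strains = [f"S{i:04d}" for i in range(n_strains)]
    rows, alleles, a1s, a2s = [], [], [], []
    for i in range(n_loci):
        chrom = CHROMS[i % len(CHROMS)]
        pos = int(rng.integers(1, CHROM_LEN))
        motif = _random_motif(rng, int(rng.choice(list(motif_lengths))))
        k = int(rng.choice(ks, p=pk))
        repeats = rng.choice(np.arange(3, 16), size=k, replace=False)
        seqs = [motif * int(r) for r in repeats]
        if k >= 3 and rng.random() < 0.15:
            # replace one allele by an equal-length substitution variant
            donor = seqs[1]
            j = int(rng.integers(len(donor)))
            alt = donor[:j] + rng.choice([b for b in BASES if b != donor[j]]) + donor[j + 1:]
            seqs[2] = alt
        if rng.random() < common_locus_fraction:
            freqs = rng.dirichlet(np.full(k, 2.0))
        else:
            alpha = np.full(k, 0.1)
            alpha[0] = 30.0
            freqs = rng.dirichlet(alpha)
        g1 = rng.choice(k, size=n_strains, p=freqs)
        het = rng.random(n_strains) < het_rate
        g2 = g1.copy()
        g2[het] = rng.choice(k, size=int(het.sum()), p=freqs)
        miss = rng.random(n_strains) < missing_rate
        g1 = np.where(miss, MISSING, g1)
        g2 = np.where(miss, MISSING, g2)
        rows.append(
            {"locus": f"STR_{i + 1}", "chrom": chrom, "pos": pos,
             "end": pos + len(seqs[0]) - 1, "motif": motif}
        )
        alleles.append(seqs)
        a1s.append(g1)
        a2s.append(g2)
    loci = pd.DataFrame(rows).set_index("locus")
    a1 = np.array(a1s, dtype=np.int32)
    a2 = np.array(a2s, dtype=np.int32)
    return StrGenotypeMatrix(
        loci=loci, alleles=alleles, a1=a1, a2=a2,
        passes=np.ones_like(a1, dtype=bool), strains=strains,
    )


def simulate_snv_panel(
    n_strains: int = 200,
    n_markers: int = 5000,
    block_size: int = 10,
    within_block_r2: float = 0.8,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Homozygous biallelic SNVs in LD blocks.

    Markers come in blocks of ``block_size``: each block has an anchor
    Bernoulli vector and the rest copy it with a flip probability tuned to
    the target within-block r2.  Returns (codes 0/1, meta with chrom/pos).
    """
    rng = np.random.default_rng(seed)
    strains = [f"S{i:04d}" for i in range(n_strains)]
    eps = (1.0 - np.sqrt(within_block_r2)) / 2.0
    codes = np.empty((n_markers, n_strains), dtype=float)
    rows = []
    pos_by_chrom = {c: 0 for c in CHROMS}
    for start in range(0, n_markers, block_size):
        p = rng.uniform(*maf_range)
        anchor = (rng.random(n_strains) < p).astype(float)
        chrom = CHROMS[(start // block_size) % len(CHROMS)]
        for j in range(start, min(start + block_size, n_markers)):
            flip = rng.random(n_strains) < eps
            codes[j] = np.where(flip, 1 - anchor, anchor)
            pos_by_chrom[chrom] += int(rng.integers(500, 5000))
            rows.append({"marker": f"SNV_{j + 1}", "chrom": chrom, "pos": pos_by_chrom[chrom]})
    meta = pd.DataFrame(rows).set_index("marker")
    return pd.DataFrame(codes, index=meta.index, columns=strains), meta


def make_transcript_table(
    n_transcripts: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Transcript metadata: gene, chrom, TSS, strand."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_transcripts):
        chrom = CHROMS[i % len(CHROMS)]
        rows.append(
            {
                "transcript": f"tr_{i + 1:05d}",
                "gene": f"gene_{i + 1:05d}",
                "chrom": chrom,
                "tss": int(rng.integers(1, CHROM_LEN)),
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    return pd.DataFrame(rows).set_index("transcript")


def simulate_expression(
    str_panel: StrGenotypeMatrix,
    transcripts: pd.DataFrame,
    truth: SimTruth,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression = intercept + planted allele shifts (+ mediator paths) + noise.

    Planted local effects shift a transcript's expression per STR genotype
    code of the planted locus (``effects`` maps code -> shift; missing calls
    get no shift).  Planted distant effects route an STR exposure through a
    mediator transcript (M = a x + noise) into target transcripts
    (T = b M + c' x + noise).  Unplanted transcripts are pure noise.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    strains = str_panel.strains
    n = len(strains)
    values = pd.DataFrame(
        rng.normal(0.0, noise_sd, size=(len(transcripts), n)),
        index=transcripts.index, columns=strains,
    )
    gcodes = np.minimum(str_panel.a1, str_panel.a2).astype(float)
    gcodes[str_panel.missing] = np.nan

    def exposure(locus: str) -> np.ndarray:
        x = gcodes[str_panel.locus_index(locus)].copy()
        return np.nan_to_num(x, nan=0.0)

    planted_targets: set[str] = set()
    for eff in truth.planted_local_effects:
        tr, locus = eff["transcript"], eff["locus"]
        if tr in planted_targets:
            raise ValueError(f"transcript {tr} planted twice")
        planted_targets.add(tr)
        shifts = eff["effects"]
        x = gcodes[str_panel.locus_index(locus)]
        shift = np.array([shifts.get(int(c), 0.0) if not np.isnan(c) else 0.0 for c in x])
        values.loc[tr] += shift
    for eff in truth.planted_distant_effects:
        x = exposure(eff["locus"])
        mediator = eff["mediator"]
        a, b = float(eff["a"]), float(eff["b"])
        values.loc[mediator] += a * x
        m_realized = values.loc[mediator].to_numpy()
        for target in eff["targets"]:
            if target in planted_targets:
                raise ValueError(f"transcript {target} planted twice")
            planted_targets.add(target)
            values.loc[target] += b * m_realized + truth.mediation_direct_effect * x
    return ExpressionMatrix(values=values, meta=transcripts.copy())


def plant_local_effects(
    str_panel: StrGenotypeMatrix,
    transcripts: pd.DataFrame,
    n_effects: int,
    delta: float = 2.0,
    min_freq: float = 0.05,
) -> list[dict]:
    """Plant allele-shift effects guaranteed to survive the common filter.

    Picks loci with at least two common genotype codes and shifts every code
    other than the smallest common one by ``delta``, so the contrast between
    common allele groups is exactly ``delta`` expression units.  Transcripts
    are paired positionally: row i of the transcript table is the target of
    locus row i (the caller places each transcript near its locus).
    """
    from .str_prep import filter_common, transform_genotypes

    codes = transform_genotypes(str_panel).codes
    planted = []
    for j, locus in enumerate(codes.index):
        if len(planted) >= n_effects or j >= len(transcripts):
            break
        vals = codes.loc[locus].to_numpy()
        res = filter_common(vals, min_freq)
        if res is None:
            continue
        _, common = res
        base = common.min()
        effects = {
            int(c): delta * (c != base) for c in np.unique(vals[~np.isnan(vals)])
        }
        planted.append(
            {"locus": locus, "transcript": transcripts.index[j], "effects": effects}
        )
    if len(planted) < n_effects:
        raise ValueError(f"only {len(planted)} plantable loci available")
    return planted


def simulate_trait(
    marker_codes: pd.DataFrame, h2_true: float, seed: int = 0
) -> pd.Series:
    """Additive polygenic trait with exact sample heritability ``h2_true``.

    Every marker gets an i.i.d. normal effect; genetic and environmental
    parts are rescaled to unit sample variances and mixed as
    sqrt(h2) g + sqrt(1-h2) e.
    """
    if not 0.0 <= h2_true <= 1.0:
        raise ValueError("h2_true must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    x = marker_codes.to_numpy(dtype=float)
    sd = x.std(axis=1)
    z = (x[sd > 0] - x[sd > 0].mean(axis=1, keepdims=True)) / sd[sd > 0][:, None]
    u = rng.normal(size=z.shape[0])
    g = z.T @ u
    g = (g - g.mean()) / g.std() if g.std() > 0 else g
    e = rng.normal(size=x.shape[1])
    e = (e - e.mean()) / e.std()
    y = np.sqrt(h2_true) * g + np.sqrt(1.0 - h2_true) * e
    return pd.Series(y, index=marker_codes.columns, name="sim_trait")


def simulate_ma_panel(
    ancestor: StrGenotypeMatrix,
    n_lines: int = 50,
    t_generations: int = 250,
    rates: tuple[float, float, float] = (1e-4, 1e-4, 1e-5),
    seed: int = 0,
    line_prefix: str = "MA",
) -> tuple[StrGenotypeMatrix, SimTruth]:
    """Mutation-accumulation panel from a single-strain ancestor.

    Each allele copy of each STR mutates independently per generation with
    the given (deletion, insertion, substitution) probabilities.  Deletions
    shorten by one motif unit (never below one unit), insertions lengthen by
    one unit, substitutions change one base at equal length.  Realized event
    counts are recorded in the truth ledger.

    The returned panel holds the ancestor as its first strain followed by
    the derived lines, sharing one allele registry per locus.
    """
    mu_del, mu_ins, mu_sub = rates
    if min(rates) < 0:
        raise ValueError("mutation rates must be non-negative")
    if max(rates) >= 1.0 / t_generations:
        raise ValueError("rates must each be < 1/t")
    if ancestor.n_strains != 1:
        raise ValueError("ancestor must be a single-strain matrix")
    rng = np.random.default_rng(seed)
    n_loci = ancestor.n_loci
    registry = [list(seqs) for seqs in ancestor.alleles]
    anc_name = ancestor.strains[0]
    strains = [anc_name] + [f"{line_prefix}_{i + 1:03d}" for i in range(n_lines)]
    a1 = np.full((n_loci, n_lines + 1), MISSING, dtype=np.int32)
    a2 = np.full_like(a1, MISSING)
    a1[:, 0] = ancestor.a1[:, 0]
    a2[:, 0] = ancestor.a2[:, 0]
    realized = {"deletion": 0, "insertion": 0, "substitution": 0}

    def mutate(seq: str, motif: str) -> tuple[str, dict[str, int]]:
        events = {"deletion": 0, "insertion": 0, "substitution": 0}
        unit = max(len(motif), 1)
        n_del = rng.binomial(t_generations, mu_del)
        n_ins = rng.binomial(t_generations, mu_ins)
        n_sub = rng.binomial(t_generations, mu_sub)
        for _ in range(n_del):
            if len(seq) > unit:
                seq = seq[:-unit]
                events["deletion"] += 1
        for _ in range(n_ins):
            seq = seq + (motif if len(motif) else seq[-1])
            events["insertion"] += 1
        for _ in range(n_sub):
            j = int(rng.integers(len(seq)))
            seq = seq[:j] + rng.choice([b for b in BASES if b != seq[j]]) + seq[j + 1:]
            events["substitution"] += 1
        return seq, events

    for i in range(n_loci):
        motif = ancestor.loci["motif"].iloc[i]
        anc_pair = (ancestor.a1[i, 0], ancestor.a2[i, 0])
        for col in range(1, n_lines + 1):
            if MISSING in anc_pair:
                continue
            new_idx = []
            for slot in anc_pair:
                seq, events = mutate(registry[i][slot], motif)
                for k, v in events.items():
                    realized[k] += v
                if seq in registry[i]:
                    new_idx.append(registry[i].index(seq))
                else:
                    registry[i].append(seq)
                    new_idx.append(len(registry[i]) - 1)
            a1[i, col], a2[i, col] = new_idx
    panel = StrGenotypeMatrix(
        loci=ancestor.loci.copy(),
        alleles=registry,
        a1=a1,
        a2=a2,
        passes=np.ones_like(a1, dtype=bool),
        strains=strains,
    )
    truth = SimTruth(mutation_rates_true=rates, realized_mutations=realized)
    return panel, truth


# ---------------------------------------------------------------------------
# Desk preset


def write_desk_fixture(outdir: str | os.PathLike, seed: int = 17,
                       n_strains: int = 200, n_loci: int = 2000,
                       n_snvs: int = 5000, n_transcripts: int = 1000) -> None:
    """Write the desk-scale TSV/BED fixture set plus truth.json."""
    from . import io_core

    os.makedirs(outdir, exist_ok=True)
    panel = simulate_str_panel(n_strains, n_loci, seed=seed)
    transcripts = make_transcript_table(n_transcripts, seed=seed + 1)
    # place each transcript near its positionally paired STR locus so the
    # planted effects fall inside local candidate windows
    k = min(n_transcripts, n_loci)
    transcripts.iloc[:k, transcripts.columns.get_loc("chrom")] = (
        panel.loci["chrom"].to_numpy()[:k]
    )
    transcripts.iloc[:k, transcripts.columns.get_loc("tss")] = (
        panel.loci["pos"].to_numpy()[:k] + 1_000
    )
    truth = SimTruth(
        planted_local_effects=plant_local_effects(
            panel, transcripts, n_effects=min(20, k // 2), delta=2.0
        )
    )
    expr = simulate_expression(panel, transcripts, truth, noise_sd=1.0, seed=seed + 2)
    snv_codes, snv_meta = simulate_snv_panel(n_strains, n_snvs, seed=seed + 3)
    io_core.write_str_genotypes_tsv(panel, os.path.join(outdir, "str_genotypes.tsv"))
    io_core.write_expression_matrix(expr, os.path.join(outdir, "expression.tsv"))
    snv_out = snv_meta.copy()
    snv_out[snv_codes.columns] = snv_codes
    snv_out.reset_index().to_csv(os.path.join(outdir, "snv_genotypes.tsv"), sep="\t", index=False)
    truth.to_json(os.path.join(outdir, "truth.json"))
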