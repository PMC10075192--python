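"""STR mutation rates in mutation-accumulation (MA) lines.

Each MA line is compared to its panel's ancestor at every STR with a
reliable (PASS, non-missing) call in both.  The two allele copies are
matched after sorting by (length, sequence); each matched pair is classed as
deletion (line allele shorter), insertion (longer), substitution (equal
length, different sequence) or none.  The per-allele, per-STR,
per-generation rate for each class is mu = m / (2 n t): m events over n
reliable STRs, t generations, two allele copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, IntervalSet, StrGenotypeMatrix

logger = logging.getLogger("estrkit")

__all__ = [
    "MaComparison",
    "pair_alleles",
    "classify_mutation",
    "compare_line",
    "mutation_rates",
    "stratify_rates",
    "compare_panels",
]

MUTATION_TYPES = ("deletion", "insertion", "substitution")


@dataclass
class MaComparison:
    """Per-line classification: locus id -> (class for allele 1, allele 2)."""

    line: str
    classifications: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def n_reliable(self) -> int:
        return len(self.classifications)

    def counts(self) -> dict[str, int]:
        flat = [c for pair in self.classifications.values() for c in pair]
        return {t: flat.count(t) for t in MUTATION_TYPES}


def classify_mutation(ancestor_allele: str, line_allele: str) -> str:
    """Length rule first: shorter -> deletion, longer -> insertion; equal
    length with different sequence -> substitution; identical -> none."""
    if not ancestor_allele or not line_allele:
        raise ValueError("allele sequences must be non-empty")
    if line_allele == ancestor_allele:
        return "none"
    if len(line_allele) < len(ancestor_allele):
        return "deletion"
    if len(line_allele) > len(ancestor_allele):
        return "insertion"
    return "substitution"


def pair_alleles(
    ancestor: tuple[str, str], line: tuple[str, str]
) -> list[tuple[str, str]]:
    """Match the two ancestor alleles to the two line alleles.

    Both calls are canonicalized by sorting on (length, sequence) and paired
    position-wise.  When both calls are heterozygous the pairing is
    ambiguous; the pairing minimizing the total mutation count is used
    (conservative: avoids manufacturing events from arbitrary matching).
    """
    a = sorted(ancestor, key=lambda s: (len(s), s))
    b = sorted(line, key=lambda s: (len(s), s))
    straight = [(a[0], b[0]), (a[1], b[1])]
    crossed = [(a[0], b[1]), (a[1], b[0])]
    n_straight = sum(classify_mutation(x, y) != "none" for x, y in straight)
    n_crossed = sum(classify_mutation(x, y) != "none" for x, y in crossed)
    return crossed if n_crossed < n_straight else straight


def compare_line(
    panel: StrGenotypeMatrix, ancestor: str, line: str
) -> MaComparison:
    """Classify both allele slots at every locus PASS and called in both."""
    ja = panel.strains.index(ancestor)
    jl = panel.strains.index(line)
    comp = MaComparison(line=line)
    for i, locus in enumerate(panel.loci.index):
        if not (panel.passes[i, ja] and panel.passes[i, jl]):
            continue
        if MISSING in (panel.a1[i, ja], panel.a2[i, ja], panel.a1[i, jl], panel.a2[i, jl]):
            continue
        seqs = panel.alleles[i]
        anc = (seqs[panel.a1[i, ja]], seqs[panel.a2[i, ja]])
        lin = (seqs[panel.a1[i, jl]], seqs[panel.a2[i, jl]])
        pairs = pair_alleles(anc, lin)
        comp.classifications[locus] = tuple(classify_mutation(x, y) for x, y in pairs)
    return comp


def mutation_rates(comparisons: list[MaComparison], t: int) -> pd.DataFrame:
    """Per-line mutation rates mu = m / (2 n t) for each mutation class."""
    if t <= 0:
        raise ValueError("generations t must be positive")
    rows = []
    for comp in comparisons:
        n = comp.n_reliable
        if n == 0:
            raise ValueError(f"line {comp.line}: no reliable STRs")
        m = comp.counts()
        row = {"line": comp.line, "n": n, "t": t}
        for typ in MUTATION_TYPES:
            row[f"m_{typ[:3]}"] = m[typ]
            row[f"mu_{typ[:3]}"] = m[typ] / (2.0 * n * t)
        rows.append(row)
    return pd.DataFrame(rows)


def stratify_rates(
    panel: StrGenotypeMatrix,
    comparisons: list[MaComparison],
    t: int,
    features: IntervalSet,
) -> pd.DataFrame:
    """Rates per genomic-feature class (feature name column of the BED).

    A locus overlapping several features counts in each; features containing
    no reliable STRs are omitted with a log note.
    """
    loci = panel.loci
    out = []
    for name in features.df["name"].unique():
        sub = IntervalSet(features.df[features.df["name"] == name])
        mask = sub.covers(
            loci["chrom"].to_numpy(), loci["pos"].to_numpy(), loci["end"].to_numpy()
        )
        in_feat = set(loci.index[mask])
        filtered = []
        for comp in comparisons:
            cls = {k: v for k, v in comp.classifications.items() if k in in_feat}
            if cls:
                filtered.append(MaComparison(line=comp.line, classifications=cls))
        if not filtered:
            logger.info("feature class %r contains no reliable STRs; omitted", name)
            continue
        rates = mutation_rates(filtered, t)
        rates.insert(0, "feature", name)
        out.append(rates)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)


def _stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    return "ns"


def compare_panels(
    rate_tables: dict[str, pd.DataFrame],
    comparisons: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests of per-line rates between panels.

    One test per (mutation type, panel pair); p-values Bonferroni-adjusted
    over every comparison made in the call.
    """
    if comparisons is None:
        names = list(rate_tables)
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for p1, p2 in comparisons:
        for typ in MUTATION_TYPES:
            col = f"mu_{typ[:3]}"
            x = rate_tables[p1][col].to_numpy(dtype=float)
            y = rate_tables[p2][col].to_numpy(dtype=float)
            if np.ptp(np.concatenate([x, y])) == 0:
                p = 1.0
                note = "all values tied"
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
                note = ""
            rows.append(
                {"panel_a": p1, "panel_b": p2, "mutation_type": typ,
                 "median_a": float(np.median(x)), "median_b": float(np.median(y)),
                 "p_value": p, "note": note}
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.minimum(out["p_value"] * len(out), 1.0)
    out["stars"] = out["p_adjusted"].map(_stars)
    return out
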