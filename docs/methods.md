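# Methods

This note documents the models, parameter choices and numerical decisions
behind `estrkit`, and what the synthetic panels do and do not establish.

## Panel model and codings

The target data are inbred, selfing strain panels: genotypes are nearly
homozygous, so one strain contributes one effective haplotype. STR calls are
diploid allele-index pairs against a per-locus allele registry (sequence and
length). Two single-number codings feed the association tests:

- **genotype coding** — the allele index; a heterozygous call `(a, b)` takes
  `min(a, b)`. With heterozygosity around 1% the information lost is
  negligible, and the reduction keeps the factor levels identical to the
  allele registry.
- **length coding** — the arithmetic mean of the two allele lengths in bp
  (half-integers possible). Distinct same-length alleles collapse to one
  level, which is the point: it separates length-driven from
  sequence-driven effects.

The **common-allele filter** keeps a locus for a given strain set only when
at least two codes each have frequency strictly above `common_allele_freq`
(default 0.05) among non-missing strains, and drops the strains carrying
rarer codes for that locus. Frequencies use the non-missing denominator (the
source material is silent on this; using called strains avoids missingness
shifting frequencies toward rejection).

The biallelic collapse for LD (`0 ↦ 0`, any positive code `↦ 1`) is applied
to the already min-reduced genotype code; how a heterozygote straddling
reference/alternative should collapse is genuinely undefined, and this is
the declared convention.

## Association test

For expression `y` over retained strains and the STR code as a factor with
`k` observed levels, the test compares one-way-ANOVA and intercept-only OLS
fits under a Gaussian likelihood:

    Λ = n · ln(RSS_reduced / RSS_full),   df = k − 1,   p = P(χ²_df ≥ Λ).

This equals twice the log-likelihood difference of the two `lm` fits
exactly. Degenerate inputs: constant expression gives Λ = 0, p = 1; an exact
full-model fit (RSS_full relatively below 1e-12) is reported as a capped
statistic (1e6) with the smallest positive double as p, keeping results
finite and sortable. Fits require `n > k + 1`. Each real test is paired with
`n_permutations_per_test` (default 1) tests on codes shuffled across the
retained strains. Simulation at n = 200 shows null p-values are uniform to
KS resolution at 1,000–2,000 tests, so the χ² reference is adequate at panel
scale; at much smaller n it is mildly anti-conservative, which the
permutation control exposes.

Candidate windows: "within 2 Mb surrounding" an anchor is read as a ±1 Mb
half-width (`local_window_bp`, `distant_window_bp`), closed boundary, with
candidate inclusion by overlap of the STR interval and distances measured to
the TSS, signed negative upstream with respect to strand. Distant candidates
are the union over the transcript's distant-eQTL regions each widened by the
window. Families (local/distant × genotype/length) are Bonferroni-thresholded
independently at `alpha_family / n_real_tests`; a merged report flags calls
found by both codings. The per-transcript top call is the minimum p, ties
broken by smaller absolute TSS distance then lexicographic locus id (a
repository convention; no rule is inherited). An optional BED mask excludes
loci in hyper-divergent regions before testing.

## LD and variance explained

LD uses per-strain 0/1 codes with heterozygous strains excluded; with `A`/`B`
the reference codes, `D = p(AB) − p(A)p(B)` and
`r = −D/√(p(A)p(a)p(B)p(b))`. r² bins at 0.7/0.3 (configurable) label pairs
high/moderate/low. Variance explained is the squared Pearson correlation of
the untransformed numeric coding with the trait; for a multiallelic STR with
opposing allele effects this underestimates the signal, so the factorial
R² (`1 − RSS_full/RSS_total`) is emitted as a secondary column. No corrected
LD estimator for binarized multiallelic markers is attempted; the
overestimation is reported, not fixed.

## Heritability

SNV preparation drops markers with any missing or heterozygous call, keeps
MAF ≥ 0.05, and prunes LD with a deterministic greedy sliding window
(window 50 markers, step 10, r² ≥ 0.8 removes the lower-MAF member, ties
drop the later position). STR markers enter the combined matrix as imputed
transformed genotype codes (loci with ≥ 2 common codes), standardized like
SNVs.

Imputation samples each locus's empirical code distribution (seeded);
iterative-PCA imputation is a documented hook but not the default — h²
claims rest on recovery tests, not on reproducing any particular imputed
matrix. Loci with ≥ 50% missing are refused.

The GRM is `G = ZᵀZ/M` with rows centered and scaled by the observed
(population) SD, giving unit mean diagonal; the inbred variant uses the
0/2-equivalent expected-binomial scaling, which for homozygous panels
doubles G and puts diagonals near 1 + F = 2. REML for
`y = μ + g + e`, `g ~ N(0, σ²g G)` profiles the ratio λ = σ²g/σ²e on a
61-point log grid over [1e-3, 1e3] refined by bounded scalar optimization,
after one eigendecomposition of G (normalized to unit mean diagonal, so h²
is scale-free). G ≈ cI is flagged unidentifiable. Recovery on block-LD
panels (n = 200, M = 2,000): mean ±0.1 of a true 0.5; null traits average
h² ≤ 0.1 (the REML truncation at 0 makes the null mean positive).

## GWA, thresholds, QTL regions, mediation

The trait is `log10(N_alt / 2·N_total)` per strain over its complete STR
calls; `N_alt = 0` is flagged undefined and excluded (a pseudocount would
distort the log scale). GWA uses the standard MLMA approximation: variance
components fit once per kinship (per chromosome under LOCO; a single
inbred-scaled kinship otherwise), then a per-marker GLS Wald test with
components fixed. BF is `−log10(α/M)`; EIGEN is `−log10(α/N_test)` with the
Li & Ji effective-test count from the marker-correlation eigenvalues
(computed on the strain-level Gram matrix, same nonzero spectrum;
eigenvalues integral to 1e-9 are snapped so exact redundancy counts
exactly). QTL regions cluster BF-passing markers within `qtl_merge_bp`
(1 kb), extend `qtl_flank_markers` (150) positions on the analyzed
(post-pruning) map, and merge overlaps.

Mediation is the linear product-of-coefficients model: `M = aX`,
`Y = c′X + bM`, estimate a·b, with a strain-resampling bootstrap (default
1,000 draws, seeded; p floored at 1/draws) and Benjamini–Hochberg
adjustment across the tested family (the adjustment method is a declared
choice). A mediator passes at adjusted p < 0.05, estimate above the 99th
percentile of all estimates, and an interpretable proportion mediated
a·b/total in [0, 1.2] — the upper tolerance exists because under full
mediation the direct-effect estimate fluctuates around zero and a strict
proportion ≤ 1 would reject about half of perfect mediators by noise alone.
`regress_out` residualizes the trait on a mediator by OLS and re-centers.

## MA mutation rates

Per line, loci with PASS, non-missing calls in both ancestor and line are
compared allele-by-allele after sorting each call by (length, sequence);
when both calls are heterozygous the pairing is ambiguous and the variant
minimizing the total mutation count is used (conservative — arbitrary
pairing would inflate rates). Classification is by length first: shorter is
a deletion, longer an insertion, equal length with different sequence a
substitution; an allele differing in both length and internal sequence is
therefore a deletion or insertion, never a substitution (logged
convention). Rates are `μ = m/2nt` with per-line `n` (reliable-site sets
are per line/ancestor pair and never shared across panels). Panel
comparisons use two-sided Wilcoxon rank-sum tests per (type, pair),
Bonferroni-adjusted over the call, with significance stars at
0.01/0.001/0.0001.

## Synthetic panels

Defaults mirror the study system at roughly 1/10 scale: 200 strains, 2,000
STRs, 5,000 SNVs, 1,000 transcripts; STR motifs 1–6 bp, 2–8 alleles per
locus, heterozygosity 1%, missingness 5%, and a configurable fraction of
loci drawing balanced allele frequencies. SNVs use a block-LD model (blocks
of 10, target within-block r² 0.8) — the minimal structure that makes LD
pruning and the EIGEN threshold non-trivial. Expression is intercept +
planted allele shifts + Gaussian noise (default SD 1, so planted
Δ = 2 is Δ/σ = 2); distant effects route an STR exposure through a realized
mediator. MA panels mutate each allele copy per generation at stated
per-type rates (deletions −1 motif unit bounded below one unit, insertions
+1 unit, substitutions one base at equal length), recording realized events.
All randomness flows from seeded generators; derived sub-streams are
deterministic.

What passing recovery tests show — and do not. The generator produces
independent strains with block LD and Gaussian noise; it has no population
structure beyond the constructed stratification fixtures, no shared
ancestry between STRs and SNVs, no expression covariance structure, and no
selection. Power and calibration results therefore validate the estimators
under their model assumptions, not performance on any particular wild
panel.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale by design:
100-fixture oracle comparisons, 1,000–2,000-test calibrations, 20 planted
effects at n = 200, h² recovery at n = 200 / M = 2,000 over 20 replicates,
GWA at 500 markers, 10-seed Wilcoxon power runs with 20 lines × 300 loci.
These sizes give the stated statistical resolution (3 SE bands, KS at 0.01)
while keeping a full run in seconds to a couple of minutes.

## CLI scope

The `estrkit` command exposes the stages with self-contained file contracts
(simulate, prep, map-local, ma-rates); the joins that are naturally built in
memory (distant mapping, effects tables, h², GWA, mediation) are driven
through the library API, which is the primary interface.
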