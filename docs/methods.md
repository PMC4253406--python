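# Methods

This note documents the statistical procedures, their assumptions, the
defaults that matter, and the choices made where the underlying study
design left the details open.

## Somatic approximation filter

Cell-line panels have no matched normal DNA, so germline variants cannot
be subtracted sample-by-sample. The filter approximates somatic status
with two rejection rules and one override, applied per normalized
(site, alt-allele) key:

1. **Population-database rejection.** Any variant whose population
   allele frequency is nonzero is treated as germline. This is a literal
   "frequency ≠ 0" rule — no minimum threshold — so a database entry at
   frequency 0 does *not* reject. Matching is by normalized genomic key
   only.
2. **Panel-recurrence rejection.** Any variant present in strictly more
   than `recurrence_fraction` (default 0.15) of the panel's lines is
   treated as an uncatalogued SNP or pipeline artifact. For a 22-line
   panel, 0.15 × 22 = 3.3, so rejection fires at 4 lines and a variant
   in exactly 3 lines survives — the rule is equivalent to "more than 3
   cell lines" at this panel size.
3. **Hotspot rescue.** Either rejection is overridden when the hotspot
   catalog contains the variant — by normalized genomic key first, then
   by (gene, protein change) when the catalog row provides only that.
   The genomic key is the stricter match and is always tried first.

When both rejections fire, the recorded reason is `population_db` (the
rules apply in that order). The kept set equals
`V \ ((P ∪ R) \ C)` and is independent of record order; the test suite
checks this against a brute-force evaluation of the set expression on
adversarial random panels.

Variant keys are 1-based VCF coordinates with flank-trimmed minimal
alleles (shared suffix trimmed before shared prefix, each keeping at
least one base). No reference sequence is consulted, so repeat-mediated
left-shifting is out of scope; the trimming alone is idempotent and is
verified against an exhaustive minimal-representation search.

Presence is binary — a genotype containing at least one copy of the alt
allele — with no depth or allele-fraction threshold. Gene mutation
frequencies count a line once per gene, over protein-altering effect
classes (everything except `synonymous` by default).

## Pseudonormal copy-number calling

Depths are per-gene mean capture depths. Each line is first scaled so
all per-line medians agree (multiplying a line's depths by a constant
therefore cannot masquerade as CNV). The **pseudonormal** baseline is
the per-gene arithmetic mean over *all* lines, including the line later
compared — self-inclusion attenuates a private aberration's ratio by at
most ~1/22 on the linear scale at the default panel size, which the
default thresholds absorb. Ratios are `log2((d+ε)/(b+ε))` with ε = 1
read, clamped to ±8.

Categorical calls use conventional exome cutoffs, exposed in config
(the study this emulates states none): homozygous deletion ≤ −1.3 <
loss ≤ −0.4 < neutral < 0.4 ≤ gain < 1.0 ≤ amplification. A single-copy
loss in a diploid background sits near log2(1/2) = −1, a single-copy
gain near log2(3/2) ≈ 0.58. Calls are strictly per gene — no
segmentation — and sex-chromosome genes can be flagged but receive no
ploidy correction.

## Differential expression

**NB exact test** (count scale, e.g. normal vs cancer). Library sizes
are equalized by scaling every sample's counts to the geometric-mean
library size and rounding; the per-sample factors are recorded. A single
common dispersion φ maximizes the summed per-gene conditional NB
log-likelihood (each group's counts conditioned on the group total,
which is exact for equal library sizes) over a log-spaced grid of 200
points on [10⁻⁶, 5]; Poisson data collapses to the grid minimum, and
simulated φ = 0.2 data is recovered within [0.15, 0.25]. Per gene, the
two group sums are negative-binomial; conditional on the gene total the
split follows a negative-hypergeometric law, and the two-sided p sums
the probabilities of all splits no more probable than the observed one
(ties counted once, no doubling). At φ = 0 this reduces to an exact
binomial split test, checked against exact-fraction enumeration. No
tagwise (per-gene) dispersion shrinkage is applied — the simplest
faithful NB exact test, cross-checked against edgeR's common-dispersion
`exactTest` (Spearman ρ ≥ 0.99 on shared fixtures).

**Moderated t** (log scale, e.g. HPV+ vs HPV−). Run on log2-CPM with a
prior count of 0.5. Gene-wise pooled variances `s²_g` with d residual
degrees of freedom are shrunk toward a prior: `s̃²_g = (d₀s₀² + d s²_g)/(d₀+d)`,
with (d₀, s₀²) estimated by matching the mean and variance of log s²_g
to a scaled log-F distribution via digamma/trigamma moments. The
statistic is referred to t with d₀ + d degrees of freedom. Forcing
d₀ = 0 recovers the ordinary two-sample t exactly; d₀ → ∞ pools all
genes to s₀². The implementation agrees with limma's `eBayes` to
machine precision on shared fixtures. Unreplicated designs are refused
with a pointer to the NB stage.

**Gating.** BH step-up FDR (monotonicity enforced, checked against the
brute-force `min_{j≥i} p_(j) m/j` definition). The NB stage gates at
|log2FC| ≥ 1 and q < 0.01; the moderated-t stage at |log2FC| ≥ 1 and
raw p < 0.05. Fold changes are ratios of group-mean CPM with a
half-count-equivalent prior.

## Combined-score enrichment

Per term: overlap k of the query with the term, Fisher's exact
one-sided p = hypergeometric P(X ≥ k) over an explicit background
universe (the universe is a required input; no implicit default is
assumed). Raw Fisher p favors large terms, so each term's observed rank
(terms ordered by ascending p) is calibrated against B = 1000 uniform
random queries of the same size: μ and σ are the mean and sample SD of
the term's rank across the draws, z = (rank − μ)/σ, and the combined
score is `c = ln(p) · z` — positive for terms enriched beyond
expectation. Scores from a down-regulated query are negated for
presentation; |c| is direction-invariant.

Two deliberate numerical choices:

- **Ties use mid-ranks.** Tied p-values are everywhere (every
  zero-overlap term has p = 1). Average ranks are deterministic *and*
  keep exchangeable terms exchangeable; a name-based tie-break would
  bias the calibration toward lexicographically early terms. Ranks are
  therefore reported as floats.
- **c is floored at 0** before the direction sign: a term ranking worse
  than its random expectation is simply not enriched. The natural log is
  used (any base rescales c uniformly; the base is recorded in the
  result metadata). σ = 0 (degenerate library) yields z = 0 and is
  flagged. BH q-values over the Fisher p are reported as supplementary
  columns.

## Synthetic data

The generators emulate the structure of a 22-line tumor-only panel
study; all are pure functions of (config, seed), with one spawned
stream per artifact so each file is independently reproducible.

- **Variant panel.** Germline variants draw allele frequencies from
  Beta(0.5, 8) (rare-skewed, as in population exome databases), clipped
  to [10⁻⁴, 0.99], and appear per line with the diploid carrier
  probability 1 − (1 − f)²; emitted records are conditioned on at least
  one carrier (a VCF row with no carriers is not a call). Artifacts are
  planted in 5–9 lines — strictly above the 22-line recurrence cutoff —
  with database frequency 0. Private somatics occupy exactly one line
  (3 per line by default). Hotspots (8) are catalogued, 25% of catalog
  rows by (gene, protein change) only, and planted in 1–12 lines so
  some exceed the recurrence cutoff and genuinely need the rescue.
- **Depths.** Each gene draws a copy state from
  {0: 0.02, 1: 0.06, 2: 0.80, 3: 0.07, 5: 0.05}; aberrant genes carry
  the state in 1–2 random lines. Depth = 100 × copy/2 × lognormal noise
  with CV 0.08 (a per-gene mean depth averages many targeted positions,
  so line-to-line variability after scaling is small); copy-0 cells emit
  2% residual background; per-line multipliers in [0.5, 2] exercise the
  median scaling. Aberrations are restricted to a couple of lines per
  gene so that pseudonormal self-inclusion stays within its documented
  ~1/11 bound; broader recurrent aberrations would attenuate ratios
  toward the thresholds.
- **Counts.** Baseline means are lognormal (median 150, log-sd 0.7),
  dispersion φ = 0.1, 30 up and 50 down genes planted at |log2FC| = 2,
  per-sample depth factors in [0.7, 1.3]. The pipeline layout is 4
  normal samples vs one sample per panel line; recovery tests use 4 vs 4.
- **Gene sets.** 50 random terms of size 50 over the count-matrix gene
  universe, plus `PLANTED_UP`/`PLANTED_DOWN` terms containing exactly
  80% of the true up/down lists (fill genes are drawn outside the source
  list so the overlap is exact).

What passing on this synthetic data does **not** show: the generators
plant clean, independent effects — no GC or mappability bias in depths,
no sample-quality outliers, no batch structure or compositional bias in
counts, no linkage between variants, and population frequencies match
the database exactly rather than being estimated from a finite cohort.
Real-panel performance therefore depends on upstream QC that is out of
scope here (alignment, variant calling, annotation are consumed, not
computed).

## Pipeline and reproducibility

Stages run in order (filter → CNV → DE → enrichment → oncoprint
summary); each stage writes its artifacts before the next begins, and a
failure aborts with the stage name, leaving earlier outputs intact. The
oncoprint table reports, per gene × line: mutation status (catalogued
hotspot vs novel), CNV category, and an expression tier — log2 of the
line's CPM against the panel median, bucketed at ±1 — for the top 30
genes by mutation frequency (the published figure's gene list is
curated; descending frequency is the algorithmic stand-in).

All outputs carry the tool version and a hash of the analysis
parameters (not the output location) in a header comment and contain no
timestamps, so identical configurations produce byte-identical files.
Problem sizes in the test suite and acceptance script (≤ 200-variant
filter panels, 2000-gene matrices, 20 seeds for recovery rates, B =
1000 calibration draws) were chosen as the smallest sizes at which the
recovery and calibration bands are stable.

## Known limitations

- The filter is an approximation: a true somatic variant recurrent in
  > 15% of lines and absent from the hotspot catalog is lost, and rare
  germline variants absent from the population database survive.
- Common-dispersion NB testing underfits genes with atypical
  biological variability; a tagwise-shrinkage extension is deliberately
  out of scope.
- The CNV caller has no purity/ploidy model and no segmentation; a
  genome-doubled line biases its own baseline contribution.
- The Monte-Carlo rank calibration is exchangeable across terms only
  under uniform random queries; structured queries (e.g. correlated
  gene families) are not modeled.
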