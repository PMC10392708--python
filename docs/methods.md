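# Methods

This note records the statistical conventions `tilscore` implements,
the generative model behind its synthetic cohorts, and the choices made
where the analysis design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Normalization and panel merge

**Reference-gene selection (geNorm).** For candidate genes on the log₂
scale, the stability of gene *j* is
M_j = mean_{k≠j} SD_samples(A_jk) with A_jk = log₂x_j − log₂x_k
(sample SD, ddof = 1). The reported per-gene M is computed against the
full candidate set; the ranking comes from iteratively excluding the
highest-M gene and recomputing among survivors. Ties eliminate the
later-listed candidate, so a zero-variance (fully degenerate) matrix
ranks by input order with all M = 0. The pairwise variation V(n, n+1)
is the SD across samples of the change in the normalization factor
(mean log₂ of the top-n genes) when the (n+1)-th gene is added; the
selected reference set is the smallest n ≥ `min_refs` (default 3) with
V(n, n+1) < `v_threshold` (default 0.15, the conventional cutoff), or
all candidates when no n qualifies.

**Housekeeping scaling.** Per-sample factors are computed on
counts + 0.5 (a pseudocount keeps geometric means finite at zero
counts, which are routine in targeted panels):
f_s = mean_{s'}(g_{s'}) / g_s with g_s the geometric mean of the
selected references in sample s. Samples with g_s below `qc_min`
(default 20) are flagged and excluded before the cohort mean — the
"too few read counts" QC rule, parameterized because no principled
universal floor exists. Scaling is monotone and positive, so
within-sample gene ordering is preserved.

**Merge.** With both panels normalized independently, the scaling ratio
is r = geomean(first panel, common probes, all samples) /
geomean(second panel, same cells). Every value of the *second* codeset
(the panel listed second in the run configuration — the analysis does
not prescribe which panel is rescaled, so the order is explicit
configuration) is multiplied by r; common probes are then averaged
entrywise on the normalized linear scale (averaging before rather than
after log transform; the alternative differs only at second order) and
unique probes carried through. Zero entries are floored at 0.5 inside
geometric means; strictly positive values are untouched, so exact
identities (e.g. merge(A, A) = A) hold to floating tolerance.

## Differential expression

The two-group test is Welch's unequal-variance t on log₂ normalized
data with Welch–Satterthwaite degrees of freedom. This is a deliberate,
documented choice: the upstream vendor pipeline this replaces does not
publish its test form, and Welch's t is closed-form, robust to
variance heterogeneity, and consistent with defining the fold change as
a difference of log₂ group means. Genes with zero variance in both
groups and equal means get p = 1. The FDR family is the endogenous
genes of the merged panel (housekeepers excluded). Benjamini–Yekutieli
adjustment — BH inflated by c(m) = Σ_{i≤m} 1/i, valid under arbitrary
dependence, appropriate for co-regulated gene panels — uses the
standard step-up monotonization. Volcano classification: up if
p_raw < 0.05 and log₂FC > 1, down if log₂FC < −1, else ns.

## Cell scores

Raw score: arithmetic mean of marker-gene log₂ expression. TIL
composite: mean of the raw scores of B cells, T cells, CD45,
macrophages, cytotoxic cells. Relative scores are computed as
*differences of log₂ scores* — the log of the ratio of geometric
means — because the raw scores are already logarithms; dividing two
log values would be dimensionally meaningless. Centering subtracts the
cohort mean per (cell type, denominator) row. Markers absent from the
merged matrix are dropped with a warning (panels differ in coverage); a
cell type losing all markers is an error. Marker maps are plain
editable TSV; no proprietary panel content is embedded.

## Group statistics

The exact RxC Fisher test enumerates the full fixed-margins fiber and
sums the multivariate hypergeometric probabilities of all tables at
most as likely as the observed one (relative tolerance 1 + 1e-7) —
the probability-mass two-sided rule of mainstream implementations;
2x2 tables follow the same rule. Totals beyond the enumeration budget
(default 10,000) raise, with a Monte-Carlo fallback sampling tables
from the permutation null. Wilcoxon rank-sum uses midranks,
tie-corrected variance, and a 0.5 continuity correction (exposed,
default on). Kruskal–Wallis is tie-corrected with a chi-square (k−1)
reference. Dunn's post-hoc z uses pooled mean-rank differences with the
tie-corrected variance N(N+1)/12 − Σ(t³−t)/(12(N−1)); pairwise p-values
are Bonferroni-adjusted over all k(k−1)/2 pairs (Dunn's original
proposal; the adjustment family is logged). Quartiles are linear
interpolation (type 7), the most common convention.

## Survival

Kaplan–Meier uses the product-limit form with censored-at-t subjects
still at risk at t. The log-rank statistic accumulates O−E with the
hypergeometric variance at each distinct event time (1 df chi-square).
Youden cutpoints evaluate J = sensitivity + specificity − 1 at
midpoints between consecutive distinct marker values, in both
orientations, with ties resolved to the lowest cutoff (deterministic,
favors larger "high" groups); value > cutoff ⇒ "high". Under censoring
the ROC positive class is "event observed during follow-up" — censored
subjects count as non-events. This is a known limitation (it ignores
follow-up length), not a time-dependent ROC. Median splits send values
equal to the median to "low". The univariate Cox fit maximizes the
Efron-tie partial likelihood (better than Breslow under moderate ties)
by safeguarded Newton iterations — step-halving on likelihood
decrease, convergence at |Δβ| < 1e-8, divergence (monotone likelihood /
perfect separation) reported as an error. Each marker is reported three
ways — continuous HR, median split, Youden split — in one consistent
row.

## Overrepresentation

One-sided hypergeometric tail P(X ≥ k) per gene set, with the universe
restricted to the endogenous genes of the merged panel: a genome-wide
universe would be indefensible for a targeted assay that only measures
immune-related genes. Adjustment across sets is Benjamini–Hochberg.
GMT is the exchange format; duplicate genes within a set are stored
once.

## Synthetic cohort generator

The generator emulates the *structure* of a two-panel immune profiling
study of a prostatectomy cohort: panel A with 770 endogenous + 10
housekeeping probes, panel B with 730 + 40 (defaults; all sizes
configurable), a configurable number of shared probes, 13 immune cell
types including the five TIL constituents, race/age/PSA/Gleason/grade
covariates with frequencies matching the emulated cohort's pooled
margins, and two censored endpoints (biochemical recurrence,
metastasis).

Generative model: each cell type c has a latent per-sample log₂
abundance a_cs ~ N(0, abundance_sd²) (default SD 1, a realistic
between-tumor spread of immune infiltrate on the log scale). Marker
genes of type c have mean baseline · 2^{a_cs} · sf_s with
baseline_count = 200 (a mid-range targeted-panel count) and log-normal
size factors sf_s (log₂ SD 0.25). Background endogenous genes get
per-gene log-normal baselines; housekeeping genes get high (mean
1,000) abundance-independent baselines. Panel B means carry a global
efficiency factor (default 1.5) so the merge ratio is exercised away
from 1. Counts are gamma–Poisson (negative binomial) with
var = μ + dispersion·μ² and dispersion 0.05, typical of targeted count
panels; dispersion → 0 recovers the Poisson, and dispersion = 0 exactly
is implemented as the deterministic rounded-mean limit, which gives
tests a noise-free reference point. Survival times are exponential
with log-hazard log(h₀) + Σ coef · score over the planted effects
(default: coefficient −1 linking the latent mast-vs-TIL score to
metastasis); censoring is independent exponential with its rate solved
numerically so the expected censored fraction equals `censor_rate`.
The master seed spawns a fixed independent substream per operation
(marker map, counts, clinical), so adding an operation never perturbs
the others and identical seeds give identical outputs.

What the generator does *not* emulate: probe-level efficiency
differences within a panel, correlated cell-type abundances, batch or
cartridge effects, non-proportional hazards, and informative censoring.
Passing tests therefore demonstrate the correctness of the analysis
machinery and its behavior under a known truth — not the biological
validity of any particular marker set on real tumors.

## Replicated simulation studies

`tilscore.simulate` fixes two canned experiments. The recovery study
uses n = 200 samples per cohort, the planted −1 mast-vs-TIL effect on
metastasis, 30% censoring, and scaled-down panels (80 + 70 endogenous
genes, 30 shared, 8 + 8 housekeepers, 3 markers per type): panel width
does not enter the per-gene model, so tens of background genes exercise
the same code path as hundreds while keeping 100 replicates cheap. The
null study uses 51-sample cohorts with a 1,000-gene endogenous union
(600 + 500 with 100 shared) and no planted effects. The measured
quantities — mean Cox beta, Youden/log-rank detection power, p < 0.05
fraction, BY zero-call rate — are recomputed at run time by
`scripts/acceptance.py` and asserted in the test suite. The mean
recovered beta sits slightly inside −1 because marker-level count noise
attenuates a regression on an estimated covariate; the attenuation is
small here since the latent abundance spread dominates the measurement
error.

## Known limitations

- The Welch-t DE model is a stand-in for an unpublished vendor test;
  results on real data may differ in the tails.
- The Youden ROC ignores censoring time (see above).
- No covariate-adjusted or multivariable models; all survival fits are
  univariate by design.
- The exact Fisher enumeration is exponential in table size; large
  tables need the Monte-Carlo fallback.
- Common probes are averaged on the linear scale after scaling;
  log-scale averaging would differ slightly for discordant probes.
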