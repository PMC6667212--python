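# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the package's known limitations.

## Design and contrasts

The experimental design is a drying time course: one tissue, ordered EWC
stages (default 35, 15, 5, 1 percent, wettest first), `r` replicates per
stage.  Stages are *design labels* — their order is declared, never
inferred from the numeric values.  Two contrast schemes are derived:

* **AR** (against reference): each later stage vs the first stage.
* **TC** (time course): each stage vs its immediate predecessor.

With `k` stages both schemes give `k−1` contrasts, labelled
Early/Middle/Late (positional names beyond three).  A two-contrast mode
(Early + Middle only) is first-class, to support designs whose terminal
stage is unusable.

## Normalization

**TMM.** The factor is defined on raw counts, so it absorbs sequencing
depth *and* composition bias: normalized counts are `counts / factor`.
The reference sample is the one whose upper-quartile count fraction is
closest to the mean upper quartile.  Against the reference, M = log₂ ratio
and A = mean log₂ abundance are computed over co-expressed genes; 30 % of
M-values and 5 % of A-values are trimmed from each tail, and the factor is
2 to the inverse-asymptotic-variance-weighted mean of the surviving
M-values.  Factors are rescaled to geometric mean 1.  Effective library
size = factor × geometric mean of column totals.

**RLE.** Median over genes positive in all samples of
count / per-gene geometric mean, taken in linear space.

Both break down on pathological inputs (a sample sharing no expressed
gene with the reference; no gene positive everywhere) and raise with a
pointer to filtering.

**Low-count filter.** A gene is kept when its count reaches `min_count`
(default 1) in at least one sample.  The threshold is configurable because
no single value is canonical; the default only removes all-zero genes.

**rlog-style transform (QC only).** log₂(normalized + 1) with per-gene
shrinkage toward the gene mean, weight `k/(k + mean count)` with `k = 10`:
low-count genes are damped toward their mean, high-count genes converge to
the plain log within 1 %.  It feeds the distance matrix and PCA, never the
tests.

## The three callers

All callers share the significance rule: call `up` iff
log₂FC ≥ +1 and BH-FDR ≤ 0.05, `down` iff log₂FC ≤ −1 and FDR ≤ 0.05,
else `ns` (both thresholds configurable).  BH adjustment is applied per
caller per contrast.  Swapping test and reference negates every log-fold
change and leaves every p unchanged.

### exact-nb (exact conditional NB test)

Counts are divided by TMM factors and rounded, equalising effective
library sizes.  The sum of `n` iid NB(μ, α) draws is NB(nμ, α/n); for two
groups sharing μ and α, the conditional law of one group's sum given the
total is negative hypergeometric — free of μ — and collapses to
Binomial(t, n₁/(n₁+n₂)) as α → 0 (the implementation switches to the
binomial branch below α = 1e−8).  The two-sided p is the probability-mass
rule: the total mass of outcomes whose probability does not exceed the
observed one (relative tie tolerance 1e−7).  Dispersion is a common
method-of-moments estimate over genes with mean ≥ 1 (median of genewise
`(var − mean)/mean²`, floored at 1e−6); optional shrinkage of genewise
estimates toward the common value with a chosen prior df is available.
The reported log₂FC uses normalized group means with a 0.5 pseudo-count.

### nb-wald (NB GLM Wald test)

Model: `x_is ~ NB(μ_is, α_g)`, `log μ_is = log s_i + β₀ + β₁·group_i`,
with RLE size factors `s_i`.  Genewise MoM dispersions are shrunk toward a
nonnegative-least-squares trend `α(μ) = a₀ + a₁/μ` with prior df 4
(moment-weighted average, floor 1e−6).  The fit is Fisher-scoring IRLS
(cap 50 iterations, deviance tolerance 1e−8), vectorised across genes;
non-converged genes are flagged and given p = 1.  The Wald statistic is
β̂₁/SE with SE² = S₀₀/(S₀₀S₁₁ − S₀₁²) from the information matrix
(equivalently 1/Σ_test w + 1/Σ_ref w, w = μ/(1+αμ)); p is two-sided
normal.  Genes with an all-zero group get a 0.25 pseudo-count on every
observation before fitting, because the unpenalised MLE sits at −∞ there
and the plain Wald statistic degenerates (Hauck–Donner); the pseudo-count
keeps such genes callable with a conservative effect estimate.  With known
dispersion the caller agrees with an off-the-shelf NB GLM to ~1e−7
(checked in the tests).

### voom-lm (precision-weighted linear model)

log₂-CPM: `log₂((count + 0.5)/(L_s + 1) · 10⁶)` on TMM-effective library
sizes `L_s`.  A genewise two-group OLS fit yields residual SDs; a lowess
curve (span 0.5) of √SD against mean log-CPM, evaluated at each
observation's fitted value, gives precision weights `1/curve⁴`.  After a
weighted refit, residual variances are moderated: `(d₀, s₀²)` are
estimated by moment-matching log-variances to a scaled-F distribution
(trigamma inversion), the posterior variance is the df-weighted average,
and the moderated t has `df_resid + d₀` degrees of freedom.  Forcing
`prior_df = 0` with unit weights reduces the caller exactly to an ordinary
two-sample t-test on log-CPM (a tested identity).  Moderated variances
always lie between the genewise and prior variances.

### Unreplicated contrasts

When both sides of a contrast have a single replicate (the terminal-stage
scenario), `exact-nb` and `nb-wald` fall back to a configured fixed
dispersion (default 0.1) and flag every result `unreplicated`; setting the
fallback to `None` makes them refuse instead.  `voom-lm` always refuses
(zero residual df).  The fallback value is a deliberate, visible prior: no
dispersion is estimable from one observation per group.

## Juries and trajectories

J1 direction conflicts (one caller `up`, another `down`, same gene and
contrast) resolve to `ns` with a logged `conflict` flag — the trajectory
partition needs a single direction per gene, and a conservative, auditable
rule beats silently preferring one caller.  Combination tables partition
the J1 set by which callers called each gene (7 non-empty subsets of
{D, E, L} = {nb-wald, exact-nb, voom-lm}); percentages are rounded half
away from zero, matching how such tables are printed.  The "all three"
cell percentage equals round(100·|J3|/|J1|) by construction.

## Enrichment

The Fisher primitive enumerates the hypergeometric support directly and
uses the probability-mass two-sided rule, which reproduces published
contingency-table p-values to printed precision; it agrees with exact
rational enumeration on all margins ≤ 60 and with an independent library
implementation on random larger tables.

Choices, each switchable:

* reference set = universe **minus** the category (`reference="rest"`);
  the whole-universe contrast is also implemented;
* only over-representation is reported as enrichment; depletion is behind
  `direction="both"`;
* BH adjustment is within each category's term list, matching per-category
  reporting, not global across categories;
* annotation propagation to DAG ancestors (is_a/part_of) is on by default
  when a DAG is supplied, and idempotent.

Contributing genes of an enriched term are exactly the category genes
annotated with it post-propagation; a category's contributing percentage
is the union across its enriched terms.  "Most-specific" terms are
enriched terms with no enriched descendant.

Mirror comparisons pair each category whose first non-ns token is `up`
with its mirror, and test each enzyme code's membership counts with the
same Fisher primitive, reporting raw p < 0.05 (no multiplicity adjustment
across codes — the screen is reported as printed in the source tables,
and the raw-p convention is stated in the output).

## Synthetic data generator

The generator emulates the staged design: NB counts with
`mean = baseline · 2^(designed AR log₂FC at stage) · library factor` and
variance μ + αμ².  Defaults are the study conditions: 4 stages × 4
replicates, effect size 2 log₂ units per designed step, dispersion 0.05,
library factors log-normal with CV 0.15 (mimicking realistic between-
sample depth variation), baselines log-uniform on [20, 2000] (the
moderately-to-well-expressed range where DE testing is meaningful after
filtering), and category weights 0.7 on `ns_ns_ns` with the rest uniform —
a DE fraction (~30 %) typical of strong-stress contrasts.  Designed
categories are re-derived from the fold changes at the declared threshold,
so sub-threshold effects are truthfully recorded as `ns`.  TC truth is
obtained by differencing the cumulative AR fold changes, keeping the two
schemes mutually consistent.  Annotation planting chooses the in-category
probability so the expected 2×2 odds ratio equals the requested odds
(infinite odds ⇒ the term exists only inside the category).

What it does **not** emulate: gene–gene correlation, length/GC bias,
outlier replicates with partial degradation, multi-modal dispersion, or
read-level artefacts.  Passing recovery/calibration tests therefore shows
the pipeline's arithmetic and decision rules are correct under the NB
model, not that real libraries meet that model.

## Problem sizes

Calibration and recovery checks run at 2,000 genes (null design and
effect-bearing design); the Monte-Carlo check of the exact conditional law
uses 10⁶ paired draws; property suites use a few hundred randomized
fixtures.  These sizes make every suite complete in seconds while leaving
binomial standard errors small relative to the asserted margins.

## Known limitations

* No multi-factor designs (single two-group contrast per test), no
  LFC-shrinkage estimators, no outlier-count replacement; numerical output
  is not bit-compatible with the R packages the callers emulate.
* The exact test's integer rounding of normalized counts is an
  approximation inherited from the conditional framework.
* Published mirror-comparison reference rows whose printed p-values are
  inconsistent with their own printed counts (two rows, by exhaustive
  laterality/typo probing) are excluded from the validation set, as noted
  in `trajdeg/refdata.py`.
* QC outlier flagging is advisory; excluding samples requires an explicit
  configuration decision.
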