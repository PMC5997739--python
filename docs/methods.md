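# Methods

## Model

Classical test theory decomposes an observed sum score as X = T + E,
with the true score T defined as the expectation over hypothetical
replications and E uncorrelated with T. Reliability is the population
quantity ρ²_XT = σ²_T / σ²_X. Because T is unobservable, reliability is
estimated through internal consistency; the package implements
coefficient alpha,

    α = n/(n−1) · (1 − Σᵢ σᵢ² / Σᵢⱼ σᵢσⱼρᵢⱼ),

and the sum-score criterion validity

    ρ_XY = Σᵢ σᵢρᵢY / √(Σᵢⱼ σᵢσⱼρᵢⱼ),

both as functions of a `CorrelationStructure` (labels, ρᵢⱼ, optional
σᵢ and ρᵢY). Everything downstream — deletion statistics, backward
selection, exhaustive search, the goal comparison — is closed-form
arithmetic on these two quantities; no raw data are needed once the
structure exists, which is what makes a published correlation table a
complete worked example.

Two consequences of the formulas drive the package's subject matter:
alpha increases with inter-item correlations, while validity (at fixed
item–criterion correlations) increases as inter-item correlations
*fall*. Scales optimized for one goal therefore tend to be poor at the
other. The apparent contradiction with ρ_XY ≤ √(reliability) is resolved
by the paradox module: alpha is only a lower bound to reliability, and
the bound becomes arbitrarily loose as items decorrelate
(`build_orthogonal_model(5, 0.8)` has reliability 0.8 and alpha exactly
0). `check_validity_bound` therefore flags a violation of
|ρ_XY| ≤ √α as evidence that alpha underestimates reliability, not as an
inconsistency.

## Modes, conventions, numerical choices

- **Standardized vs covariance mode.** When no SDs are supplied all
  σᵢ = 1 and alpha reduces to the standardized form n·r̄/(1+(n−1)r̄).
  The bundled table published only correlations, so it is analyzed in
  standardized mode; reproducing its printed raw-data quantities exactly
  (the corrected item-total column, the prediction scale's validity .40)
  would require the unpublished item SDs, and the unit-SD recomputations
  (e.g. 0.392 for that validity) agree only to about a point. Both modes
  are supported for user data.
- **Binary criteria** are handled as ordinary Pearson (point-biserial)
  correlations; the validity formula is applied unchanged.
- **Alpha may be negative**; it is reported as computed, never floored,
  since a negative value is itself diagnostic.
- **Non-PSD inputs.** Rounded published matrices can be slightly
  indefinite; a structure whose smallest eigenvalue is below −1e−8
  triggers a warning but is analyzed as written. Symmetry is enforced to
  1e−12, the diagonal must be exactly 1, missing entries are an error.
- **Selection determinism.** Deletions (and exhaustive candidates) that
  tie within 1e−12 resolve to the earliest item in the structure's
  declared order. Deletions within 0.01 of the winner are recorded as
  near-tie warnings in the trace, because with two-decimal input
  correlations such steps are rounding-sensitive: on the bundled table
  the greedy searches reach final sets differing from the published ones
  in one to two members while matching the published headline statistics
  at two decimals.
- **Stop rules.** Backward selection stops at a target size k, or — when
  a threshold is given instead — as soon as the objective value is at
  least the threshold (a pool that already satisfies it is returned
  unchanged); k wins when both are given. A threshold that is never
  reached terminates at the minimum scale size of 2 with a warning flag.
- **Enumeration cap.** Exhaustive search refuses pools with more than
  10⁶ candidate subsets at the requested size and reports the total
  subset count in the refusal.

## Synthetic data generator

`simulate_sample` emulates a screener pretest: continuous item responses
are loading-weighted scores on correlated standard-normal factors plus
unique noise (unit total variance), discretized at per-item thresholds
into four Likert categories 0–3; the default thresholds are the
standard-normal quartiles, giving equal category probabilities. The
binary criterion is a liability — factor-weighted plus independent
noise — thresholded at its own (1 − prevalence) population quantile.
One seeded `numpy` generator drives each run; identical design and seed
give byte-identical output.

The default design (`default_design`) is the package's emulation of the
worked example's setting: 242 respondents, ten items on two factors
correlated 0.4 (six items on one factor, four on the other, loadings
spread over 0.5–0.8), criterion loading equally on both factors with a
unit-variance liability, prevalence 0.25. The source study did not
publish its diagnosis prevalence, item SDs, or which items were used, so
these values are a realistic emulation of a depression-screener
validation sample, not a replication, and the prevalence is
configurable.

Population targets for recovery tests come in two forms:
`design_implied_structure` gives the latent continuous correlations
ΛΦΛ′ + uniquenesses, and `discretized_structure` gives the exact Pearson
correlations, SDs, and point-biserial criterion correlations of the
*discretized* scores, computed from bivariate-normal rectangle
probabilities over all threshold pairs. Sample estimates converge to the
discretized values (the suite checks agreement within 0.02 at
n = 10⁵); the latent values are systematically larger, which is the
ordinary attenuation of coarse categorization.

What the generator does not emulate: item-specific category
distributions (skewed real PRO items), missing data, response styles,
test–retest structure, or any item-response-theory mechanism. Passing
recovery and trade-off tests therefore show that the estimators and
searches behave correctly under a faithful factor-model data process,
not that real questionnaire data satisfy that process.

## Experiment sizes

The trade-off experiment defaults used in tests and examples — 20
replications of n = 242 at k = 5 — keep the full suite in seconds while
making the arm ordering (mean alpha higher in the measurement arm, mean
validity at least as high in the prediction arm) stable across seeds;
recovery checks use a single n = 10⁵ sample, for which Monte-Carlo error
on a correlation is about 0.003.

## Known limitations

- No sampling variance or confidence intervals for alpha or validity;
  values are treated as population quantities of the supplied structure.
- No correction for chance capitalization in selection: with many items
  and modest n, in-sample optimized validity is optimistic.
- Greedy backward elimination is not guaranteed optimal (the suite
  asserts only greedy ≤ exhaustive); forward selection is not
  implemented.
- Pearson correlations on integer scores throughout; no polychoric
  option.
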