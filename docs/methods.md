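# Methods

This note documents the statistical procedures survrake implements, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Calibration weighting

**Post-stratification.** Units in cross-classification cell *c* receive
`w_i = N_c / n_c`. The estimator is exact for the joint distribution of the
cell characteristics but undefined when a populated cell has no sampled
units; we raise an error listing the offending cells rather than collapsing
cells silently, because any collapse changes the estimand. The canonical
configuration is sex × 9 five-year age bands × 4 remoteness categories
(72 cells), which needs cohort-scale samples (tens of thousands) to keep
every cell occupied.

**Raking.** Iterative proportional fitting on unit records: initialise
`w_i = population_total / n` (the study design supplies no sampling weights,
so the uniform start is the only defensible one), then sweep characteristics
in the order they appear in the margin set, scaling category *j* of
characteristic *k* by `T_kj / Ŵ_kj`. Convergence is declared when the
maximum relative margin error is below `tolerance` (default 1e-6, max 200
sweeps). IPF on categorical margins converges geometrically whenever the
margins are compatible with the sample's support; non-convergence almost
always signals structural incompatibility, so it is surfaced as an error
carrying the worst margin rather than a warning. At convergence every margin
matches its control total to the tolerance and the weights sum to the
population total.

**Trimming.** After convergence, weights outside `median ± m·IQR` (default
multiplier m = 6) are capped and the sample re-raked, cycling up to 10 times;
if weights still exceed a freshly computed bound the fit returns with a
warning flag instead of failing. The rule is exposed two-sided, but the lower
bound `median − 6·IQR` is non-positive for any realistically dispersed weight
distribution, so lower trimming is ordinarily inert. Quartiles use linear
interpolation between order statistics (numpy's default, the "type 7"
convention); the trim bound depends on the quartile convention, so it is
fixed and documented. Whether the original procedure trimmed once or cycled
is not determinable from public sources; cycling until stable is the more
conservative reading and is recorded in the weight provenance
(`trim_count`, `within_trim_bound`).

Both weighting methods are exposed as scikit-learn estimators (`Raker`,
`PostStratifier`: configure in the constructor, `fit(X)` learns `weights_`,
`get_params`/`set_params` compose with sklearn tooling), with
`rake()`/`poststratify()` as functional wrappers returning a `WeightVector`
carrying provenance. The estimation and incidence stages are summaries rather
than fit/predict models and are plain functions returning result objects.

## Prevalence estimation

Weighted prevalence is the Hajek ratio `p̂ = Σ w_i y_i / Σ w_i` per category,
with the single-stage with-replacement linearisation variance
`var = n/(n−1) Σ_i (w_i(y_i − p̂)/Σw)²` — the default behaviour of survey
software for a weighted proportion under one-stage WR sampling, and the
assumption-light choice when the true selection mechanism is unknown. CIs are
`p̂ ± t_{0.975, n−1}·SE`, truncated to [0, 100]% (a z quantile is available
via `use_t=False`); the margin of error is the distance from the point
estimate to a limit. Missing values form their own reportable category but
are excluded from weighting and from effectiveness comparisons.

Effectiveness against a benchmark survey is summarised by four descriptive
measures per scheme: (1) categories with overlapping 95% CIs — closed-interval
overlap, so touching intervals count, and the measure is skipped when the
benchmark carries no CIs; (2) categories with the benchmark point inside the
study CI; (3) categories whose weighted point estimate moved strictly closer
to the benchmark than the unweighted one — computed on unrounded estimates,
because 1-decimal rounding would make ties common and the strict inequality
then under-counts; (4) median and IQR of absolute differences. Benchmark
waves are averaged arithmetically (CIs bound-wise only when all waves have
them). Study categories absent from the benchmark are dropped with a logged
notice rather than an error, since benchmark questionnaires rarely cover
every study category.

## Incidence and standardisation

Follow-up runs from `max(entry, window start)` to
`min(diagnosis, death, window end)` on a decimal-year axis and is split
exactly at 5-year age-band boundaries (Lexis expansion on age), so band
person-years sum to raw follow-up to machine precision. Bands are half-open
`[lower, upper)`: an event exactly on a birthday boundary belongs to the band
being entered. Prevalent cases (diagnosis at or before entry) must be
excluded upstream and are rejected loudly.

Expected counts apply reference sex-age-specific rates to weighted
person-years: `E = Σ_i w_i Σ_s λ_s py_is`. Reference rates are treated as
known constants — whole-of-population denominators are an order of magnitude
larger than any cohort, so their sampling variance is negligible relative to
the cohort's. The weighted observed and expected totals and their
variances/covariance use the same with-replacement linearisation as the
prevalence estimator, and the SIR confidence interval is Fieller's: the roots
of `(E²−z²V_E)θ² − 2(OE−z²C)θ + (O²−z²V_O) = 0` with z = 1.959964 at
α = 0.05 (a normal rather than t quantile; the effective df of cohort-scale
totals make the difference negligible). All three second-moment terms are
exposed, plus a `fixed_expected` mode (V_E = C = 0) for sensitivity analysis.
A `max_age` option truncates follow-up (and the band set) below a cutoff —
the robustness check relevant for designs that deliberately over-sample the
very old. Direct age-standardised rates against a fixed standard population
(`Σ (d_a/PY_a)·W_a / ΣW_a`, per 100,000) are provided for registry-style
comparisons.

## The synthetic cohort generator

The generator defines the study conditions under which everything is tested:

- **Population.** Seven categorical demographics with the published 2006 NSW
  census category shares as marginals. The joint distribution is an
  independence model perturbed by declared pairwise log odds-ratios (older
  age with widowhood and lower formal education, non-Australian birth with a
  language other than English, remoteness with Australian birth) and then
  calibrated back to the declared marginals by IPF of the joint cell table —
  the same engine used for raking, so associations can be injected without
  moving margins. Ages are continuous within the realised 5-year band; the
  open 85+ band gets an exponential tail (mean 4 years). Three binary
  outcomes (current smoking ≈ 15%, fair/poor health ≈ 15–18%, obesity ≈ 20%)
  follow logistic models loading on age, education, residence and marital
  status, so they correlate with — but are not determined by — the weighting
  demographics.
- **Selection.** Unit propensities `expit(logit(base_rate) + Σ effects)`
  with base rate 0.18 (a realistic volunteer-cohort response rate). The
  default mechanism over-samples ages 80+ and remote/rural residents and
  the university-educated, and under-samples current smokers and people in
  fair/poor health — the qualitative bias structure of volunteer cohorts. A
  `demographic_selection_spec` variant restricts effects to the seven
  weighting characteristics, the controlled condition under which full
  raking can correct selection bias exactly in expectation.
- **Follow-up.** Piecewise-exponential hazards per cancer (lung, colorectal,
  female breast, prostate) and for all-cause death, constant within sex ×
  age-band strata, multiplied by per-unit frailty rate ratios (smoking ×8 on
  lung by default). The synthetic rate tables are plausible stand-ins shaped
  like registry incidence for a 45+ population, not any registry's numbers.
  Events are simulated from entry to the calendar window end; the
  whole-population follow-up doubles as the registry analogue from which
  reference rates are measured (`rates_from_cohort`).

What the generator does **not** emulate: the real joint demographic
distribution (only its margins and a few declared associations), item
non-response patterns (missingness is injected independently per field),
competing detail such as multiple primaries or death-certificate-only cases,
and secular trends in rates within the window. Passing tests therefore show
that the estimators recover truth under a known, plausibly shaped selection
and hazard structure — not that any particular real cohort is corrected.

## Experiment sizes and numerical choices

Simulation scales were chosen for clear statistical power at interactive run
times: populations of 50,000–280,000 persons, cohort samples of roughly
3,000–55,000, 1,000 replicates for CI coverage, 300 for null-SIR coverage,
200 for parameter recovery, 20 for the effectiveness-ordering check.
Deterministic seeding flows through a single integer per operation;
replicate seeds are derived arithmetically and kept below 2³¹.

Other fixed choices: dates cross CSV boundaries as ISO-8601 and live in
memory as decimal years (exact band arithmetic; day-resolution round trip);
margin files are validated to 0.5 counts per category (printed-percentage
margins are proportionally rescaled to the population total on construction);
reporting rounds half-even to one decimal while all comparisons use unrounded
values; a 1e-9 age nudge in the hazard simulation prevents degenerate
segments at band boundaries.

## Known limitations

- Raking corrects only the component of selection bias explained by the
  calibrated characteristics; the recovery experiments quantify exactly this
  gap (the biased-cohort lung SIR moves toward but not onto 1 when selection
  acts directly on smoking).
- The Fieller interval relies on normal approximations of the weighted
  totals; below ~30 events its coverage drifts from nominal (the
  Poisson-agreement test shows ~6% bound deviation at 25 events).
- Post-stratification requires every populated cell sampled; with 72 cells
  and rare categories (remote residence, 0.6% of NSW) this binds below
  roughly 20,000 sampled units under the default conditions.
- `weighted_prevalence` treats weights as fixed; the extra variability from
  estimating the weights is ignored, as is conventional for calibration
  estimators.
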