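# Methods

This note documents the statistical machinery in `episcore`, the modeling
choices behind the synthetic-data generator, and the numerical conventions
that matter for reproducing results.

## Differential expression (module `diffexpr`)

The two-class test uses the SAM-style statistic per probe

    d = (mean_1 − mean_2) / (s + s0),

where `s` is the pooled standard error of the group-mean difference and
`s0` a single fudge factor shared across probes, set to the median of the
per-probe pooled standard errors.  Two choices deserve explanation:

* **d is computed on log2 signals.**  Microarray noise is multiplicative:
  on the linear MAS5-like scale a probe's standard error is proportional to
  its baseline, so an absolute-scale `s0` (median SE) dominates the
  denominator for every probe in the lower half of the baseline
  distribution and erases their power.  On the log2 scale the noise is
  homoskedastic, one `s0` treats all probes equally, and `d` becomes
  exactly invariant to a global rescaling of the array.  The fold-change
  filter is still applied to the ratio of *linear-scale* group means
  (`ratio ≥ 2` with BH-adjusted p ≤ 0.05), matching how such signals are
  reported.
* **The permutation null is pooled across probes by default.**  Group
  labels are permuted (all C(n1+n2, n1) arrangements enumerated exactly
  whenever that count is ≤ 10,000 — e.g. 70 for a 4 vs 4 design) and the
  two-sided p of a probe is the fraction of pooled null |d*| values, over
  all probes and arrangements, at or above its observed |d|.  With only 70
  arrangements a per-probe p can never go below 2/70 ≈ 0.029, which makes
  Benjamini–Hochberg adjustment powerless over any genome-scale probe set;
  pooling (the standard SAM device) refines the resolution to 1/(70·m).
  The per-probe exact null remains available (`null_mode="probe"`), where
  p-values are exact multiples of 1/70 at 4 vs 4.

Gene-level Venn logic collapses probes to genes by the "any probe passes"
rule; unmapped probes are logged and excluded, never silently dropped.

## Survival machinery (module `survival`)

Kaplan–Meier estimation, log-rank testing and Cox proportional-hazards
fitting are delegated to lifelines; the module adds the package's
conventions on top:

* median survival is the first time with S(t) ≤ 0.5 and "not reached"
  (`inf`) is a first-class value, since meaningful risk groups routinely
  never drop to 0.5;
* Cox fits use the Efron tie correction (cohorts of hundreds of patients
  with monthly times always contain ties); a Breslow fit (scikit-survival)
  is available for cross-checks, and the two agree exactly on tie-free
  data;
* missing covariates are handled by listwise deletion with logged counts;
* monotone likelihoods (perfect separation) are flagged `converged=False`
  with the coefficient capped at |β| = 15, never raised;
* the score test of the partial likelihood at β = 0 is implemented
  directly (`cox_score_test`); for a binary covariate on tie-free data it
  reproduces the log-rank chi-square to machine precision, which the test
  suite uses as a cross-implementation identity.

`cox_table` runs the uni/bi/multivariate comparisons (one fit per
covariate, per pair, or one joint fit) and flags covariates retaining
p < 0.05, plus near-collinear pairs (|r| > 0.999).

## Maximally selected cutpoints (module `maxstat`)

For marker x and candidate cutpoint c the scan computes the two-sample
log-rank statistic of (x ≤ c) vs (x > c),

    Z(c) = U(c) / sqrt(V(c)),

with U the observed-minus-expected event count in the low group and V the
hypergeometric variance accumulated over event times, so Z(c)² is exactly
the two-group log-rank chi-square at that split.  Candidates are the
distinct observed values whose empirical CDF lies in [q_lo, q_hi]
(default 0.10–0.90).  The selected cutpoint maximizes |Z|; ties break
toward the smaller value, and values equal to the cutpoint fall in the low
group — the same convention the ±1 score weighting uses.

Because c is chosen to maximize |Z|, the naive χ²₁ p-value at the selected
split is strongly anti-conservative (≈ 40% rejections at α = 0.05 under
the null with the default candidate window).  Two corrections are offered:

* **permutation (default, B = 999)**: the entire scan is re-run on B
  permutations of the survival data against the fixed marker, and
  p = (1 + #{perm max ≥ observed}) / (B + 1).  Assumption-free and
  self-calibrating; the scan is vectorized over cutpoints and permutation
  batches (float32 accumulation of the integer-valued risk-set counts;
  observed scans use float64), keeping a 1000-probe screen with B = 999 at
  n = 100 patients around a minute or two on one CPU.
* **approximation**: the improved-Bonferroni normal bound
  p ≈ φ(b)(b − 1/b)·log[q_hi(1−q_lo)/(q_lo(1−q_hi))] + 4φ(b)/b, reported
  as min(1, max(formula, naive p)) so the selection penalty
  (corrected ≥ naive) holds for every b.

`screen_probes` applies the scan per probe, BH-adjusts the corrected
p-values across probes, keeps probes with adjusted p ≤ 0.05, dichotomizes
each kept probe at its cutpoint and fits the univariate Cox model for
β and HR; HR < 1 labels the probe *good*, HR > 1 *bad*.  The probe set —
not the gene — is the unit of testing throughout; gene-level collapsing
happens only in reporting.

## The ±β risk score (modules `risk_score`, `model`)

The score is the sum of training-cohort Cox β coefficients signed by each
probe's position relative to its cutpoint (+1 strictly above, −1 at or
below).  Its attainable range is [−Σ|β|, +Σ|β|]; flipping one probe across
its cutpoint moves the score by exactly 2β_g.  The score cutpoint θ is
selected by the same maxstat engine applied to the score vector itself.
Validation re-estimates nothing: per-probe cutpoints, βs and θ transfer
frozen.  Models serialize to schema-versioned JSON and round-trip
losslessly; the shipped published models (25-probe decitabine/Mu-DM,
61-probe quisinostat/Mu-HA) carry β = ln HR from the printed hazard ratios
but no cutpoints (never published), so scoring them requires
`with_cutpoints`.

`PrognosticScoreModel` / `PrognosticScoreResults` wrap the
screen → build → θ → stratify sequence in a statsmodels-style
model/results pair with `summary()`, `stratify()`, `validate()` and
`plot_km()`.

## Downstream evaluation (module `evaluation`)

* Response prediction: sensitivity = P(high score | non-responder),
  specificity = P(low score | responder), two-sided Fisher exact test on
  the 2×2 table.
* Score vs ordinal grouping (e.g. proliferation-index low/medium/high):
  Spearman rank correlation — the grouping is ordinal, so a rank
  correlation is the defensible default; the choice is a package decision,
  not an external prescription.
* Subgroup comparisons: two-sided Mann–Whitney of the focal subgroup
  against each other subgroup with BH adjustment, per-group median and
  10–90 percentile summaries, and an optional flag for medians above a
  supplied score cutoff.  Groups under 3 samples are excluded with a
  warning.

## Synthetic data (module `simulate`)

The generator reproduces the statistical structure the analysis assumes,
not array physics:

* **Expression**: lognormal noise around per-probe baselines, baselines
  themselves lognormal (median signal 100, one decade spread either way —
  a MAS5 "scale 100" profile).  Signals are positive and right-skewed;
  planted probes multiply the treated-arm mean by the fold effect, so the
  expected ratio of group means equals the planted fold.  The baseline
  profile of a survival cohort's probe universe is *fixed across cohorts*
  (a platform property): this is what makes training-frozen absolute
  cutpoints meaningful on an independent validation cohort, exactly as
  they are for consistently normalized arrays.
* **Survival**: exponential proportional hazards.  Patient i's hazard is
  `baseline_hazard · exp(Σ_g β_g · 1{x_ig > cutoff_g})` over the planted
  probes; censoring is uniform U(0, b) with an administrative cap at the
  follow-up horizon, b solved numerically so the expected censored
  fraction matches the requested rate given the realized hazards.
  Defaults: baseline hazard 0.015/month (median OS ≈ 46 months for an
  unaffected patient), 30% censoring, 120-month horizon.
* **Response labels**: the sensitivity/specificity targets plus the fixed
  high-risk fraction h jointly determine the non-response prevalence
  π = (h − (1−spec)) / (sens − (1−spec)); labels are drawn per patient
  from the implied conditional probabilities.  h outside (1−spec, sens)
  is rejected as incompatible.
* **Truth tables** (planted probe, cutoff, β, direction) are returned
  alongside the data so recovery tests never re-derive ground truth.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: probe-level hybridization artifacts, batch
and normalization effects, correlated co-expression modules (planted
probes are independent), non-proportional hazards, informative censoring,
and cohort heterogeneity in platform scaling.

### Marginal attenuation of planted effects

With many *independent* multiplicative hazard effects planted at once, the
univariate (marginal) effect of each probe is attenuated: the other
probes act as unobserved frailty, and the high/low marginal hazard ratio
shrinks toward 1 over follow-up.  With 20 planted probes at |β| = ln 3 and
median cutoffs, the marginal dichotomous β observed at n = 400 is
typically 0.4–0.8, not 1.10.  This is a property of the generating model,
not an estimator defect (a single planted probe is recovered within ±0.1
at n = 2000).  The recovery benchmark therefore uses compact cohorts in
which the planted probes are the screened universe, measuring the screen's
power against exactly this attenuated signal; null calibration of the
screen is benchmarked separately on 1000 effect-free probes.  In real
cohorts prognostic genes are co-expressed rather than independent, so
their joint hazard spread — and hence the attenuation — is milder than
this worst case.

## Numerical conventions and problem sizes

* All stochastic procedures take explicit integer seeds; identical seeds
  give bit-identical results, and the pipeline runner refuses configs with
  unseeded stochastic stages.
* Exact enumeration replaces sampling whenever the label-arrangement count
  is ≤ 10,000.
* BH adjustment everywhere is the standard step-up procedure
  (statsmodels).
* Simulation studies in the test suite and acceptance script use sizes
  chosen to give stable Monte-Carlo estimates on a single CPU in minutes:
  200 random datasets for the scan-vs-oracle identity, 500 replicates at
  n = 2000 for Cox bias/coverage, 1000 probes for null calibration of both
  screens, 100 validation cohorts for generalization, and 20-probe/400-
  patient planted cohorts for recovery.

## Known limitations

* The maxstat approximation formula is asymptotic; at very small event
  counts the permutation method is the trustworthy option (and the
  default).
* `s0` uses the median-SE simplification rather than the percentile search
  of the original SAM; on log-scale homoskedastic data the difference is
  immaterial, on raw linear signals it would not be.
* Breslow fits via scikit-survival report no standard errors (used for
  coefficient cross-checks only).
* Probe-to-platform liftover between array generations, continuous
  (non-±1) score weights, and time-varying or stratified Cox models are
  out of scope.
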