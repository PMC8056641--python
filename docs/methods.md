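# Methods

## Synthetic cohorts

`gaclock.simulate` generates the data every other stage is tested on.
Gestational age is drawn from a truncated normal (defaults: mean 281 d,
sd 13 d, support 216–301 d — a term-centred birth-cohort distribution;
only the range and median of such cohorts are typically published, so the
sd is a modelling choice) and rounded to whole days. A configurable
number of "active" CpGs drift linearly with GA on the logit(beta) scale:

```
logit(beta_ij) = a_j + s_j · (GA_i − 281) + ε_ij ,   ε_ij ~ N(0, noise_sd²)
```

with baselines `a_j ~ N(0, 1)` and slopes of fixed magnitude `effect_sd`
(units: logit-beta per day) with random sign. Inactive probes are baseline
plus noise. The inverse-logit keeps every beta strictly inside (0, 1).
Modelling the signal on the logit scale while the clock is fitted on the
beta scale mirrors practice: clocks regress GA on bounded beta values.

Fixed-magnitude slopes make the **signal fraction** — the R² between GA
and the optimal linear read-out of the active probes — an exact function
of the configuration: `SNR = Var(GA)·n_active·effect_sd²/noise_sd²`,
signal fraction `SNR/(1+SNR)`, with `Var(GA)` the exact truncated-normal
variance. `SimConfig.for_signal_fraction(0.8, ...)` inverts this.

ART samples (default 45% of the cohort, reflecting a roughly balanced
ART/non-ART study design; 50% ICSI, 25% frozen transfers) receive
laboratory dates constructed so that the ETD rules recover the true GA
exactly, including fresh transfers with the retrieval date deliberately
unrecorded (insertion = retrieval + 2 days) and frozen transfers with a
2–6-day culture period and 30–180-day storage. A GAA effect is injected
by shifting the *methylation-implied* GA of ART samples
(`gaa_shift_days`) while their clinical GA stays at truth — acceleration
is by definition a DNAm-vs-clinical discrepancy.

Probe structure (active set, slopes, baselines) depends only on `seed`;
per-sample noise also depends on a `replicate` index. This lets one clock
trained on replicate 0 be applied to hundreds of independent cohorts from
the same population, which is how the GAA type-I-error experiment avoids
retraining 500 clocks.

What the generator does **not** emulate: probe-type chemistry differences,
batch effects, cell-composition heterogeneity, genetic covariance between
CpGs, or non-linear GA trajectories. Passing tests therefore demonstrate
correctness of the machinery under the stated statistical model, not
clinical performance on real cohorts.

## Probe QC and imputation

Filters run in a fixed order — cross-reactive, detection-p failures,
SNP-overlap, non-autosomal — so per-stage removal counts are
deterministic. The default detection rule fails a probe whose detection
p-value exceeds 0.01 in *any* sample; the published alternative
(exceeds the threshold in ≥25% of samples) is available as
`detp_fraction=0.25`. Missing betas are imputed with the per-probe median
across samples; probes with no observed values fall back to a supplied
median map (typically a clock's training medians) or fail loudly.

## Lasso solver

The clock is fitted by pathwise active-set coordinate descent on

```
(1/2n)·Σ_i (y_i − b0 − x_i'b)² + λ·Σ_j |b_j| ,
```

with the intercept unpenalised and predictors centred and scaled to unit
population sd before penalisation (coefficients are reported on the beta
scale). Each λ solve iterates coordinate sweeps over the current active
set to stationarity, then makes a full KKT pass to admit violators;
`λ_max = max_j |⟨x̃_j, y−ȳ⟩|/n` gives the null model. Warm starts along a
decreasing 100-point log-spaced grid (down to 0.001·λ_max) make 10-fold
cross-validation affordable; the inner kernel is numba-compiled. CV fold
assignment is a seeded random partition into near-equal folds without
stratification. The CV path uses a relaxed sweep tolerance (1e-5 on the
standardised-coefficient change) since it only ranks λ values; the final
fit uses 1e-10 and is KKT-verified at 1e-6 in tests. λ is chosen by the
CV-minimum rule by default; the one-standard-error rule is available
(`lambda_rule="1se"`) — published clocks do not state which rule they
used, and their λ values are data-dependent and not recoverable.

At prediction time, clock CpGs absent from the target matrix are imputed
from the clock's training medians when available and excluded otherwise,
matching how published clocks are applied to platforms lacking some of
their CpGs; missing cells of present CpGs use the target dataset's own
per-probe median first.

## MM-type robust evaluation

Predicted GA is regressed on clinical GA with an MM estimator:

* **S-step** — 500 seeded 2-point subsample candidates (plus the
  least-squares line as a safety candidate) scored by the 50%-breakdown
  bisquare M-scale (c = 1.548, E[ρ] = 1/2 under the Gaussian). Candidates
  are screened by median absolute residual and the best 20 get the full
  scale iteration (the fast-S screening idea); the winner is refined by
  IRLS with scale updates. Its M-scale is the reported **SE** in days —
  the robust residual scale is the only per-fit dispersion reported
  alongside R², so this is the interpretation adopted.
* **M-step** — bisquare IRLS (c = 4.685, 95% Gaussian efficiency) at the
  fixed S-scale, converging when the maximum relative coefficient change
  is < 1e-7 (≤200 iterations); non-convergence is flagged, not raised.

**R²** is the weight-based robust formulation
`1 − Σw r² / Σw (pred − p̄_w)²` with the M-step's final weights (a plain
squared-correlation option exists behind `r2_method="correlation"`);
it is clipped to [0, 1]. **MAD** is the raw median absolute prediction
error in days, deliberately without the 1.4826 Gaussian consistency
factor. A perfectly collinear input (zero residual scale) is handled as
an exact fit rather than an error. The regression direction is predicted
on clinical; the transpose direction is a one-line swap if a user prefers
it for plotting.

## Paired bootstrap

Metric differences between two prediction sets for the same individuals
are assessed by resampling individuals with replacement once per
replicate and evaluating both prediction sets on that same resample
(1000 replicates by default); models are never refit. CIs are empirical
2.5/97.5 percentile intervals; a difference is significant when its
interval excludes zero. Replicates where the robust fit fails (e.g. a
resample with constant clinical GA) are dropped and counted, with a
warning above 5%.

## GAA

GAA is the OLS residual (with intercept) of predicted on clinical GA —
deliberately *not* the MM fit, preserving the convention that the robust
fit is for evaluation and the acceleration residual is a plain linear
regression. The association test is a maximum-likelihood logistic
regression of the binary group on GAA with the Wald p-value for the GAA
coefficient; ART and non-ART samples are pooled in one residual fit.
Perfect separation is flagged and the p-value reported as not estimable.
Subgroup contrasts (IVF vs ICSI, fresh vs frozen) reuse the same test
with relabelled groups.

## ETD rules

For ART records, in whole days: fresh with a retrieval date,
`GA = (birth − retrieval) + 14`; fresh without one,
`GA = (birth − insertion) + 16` (insertion is assumed to follow
retrieval by two days); frozen,
`GA = (birth − insertion) + 14 + (freeze − retrieval)`, the last term
being the embryo's pre-freeze culture time (non-negative by the record's
date-ordering invariant). The two fresh rules agree exactly whenever
insertion = retrieval + 2. Intrauterine-insemination conceptions count
as non-ART and are rejected. All arithmetic is integer days; the 14-day
convention is applied after any rounding of dates to days.

## Numerical and design notes

* Experiment problem sizes (e.g. n = 800 × p = 5000 with 30 active CpGs
  for support recovery; 200 replications × 300 bootstrap resamples for
  interval coverage; 500 cohorts for test size) were chosen as the
  smallest sizes at which the Monte-Carlo error is well inside the
  property bands being checked.
* All randomness flows through `numpy.random.default_rng` seeds; every
  simulation, split, fold assignment, subsample draw and bootstrap is
  reproducible from its seed, and pipeline reports embed the config hash
  and seed so identical configs give byte-identical outputs.
* The bootstrap-coverage experiment uses n = 150 individuals per
  replication, a realistic held-out test-set size for this kind of study.
* `ClockModel.training_medians` may be empty (clock files from external
  sources rarely ship them); when non-empty it must cover every clock CpG.

## Known limitations

* The MM estimator is univariate (predicted vs clinical GA), which is all
  the evaluation needs; it is not a general multiple-regression MM.
* The logistic GAA test is unadjusted; maternal covariates (BMI, parity,
  smoking) are out of scope.
* No IDAT parsing or within-array normalisation (BMIQ etc.); the package
  starts from a beta matrix.
* Synthetic validation bounds what the tests can claim about real data —
  see the generator's non-goals above.
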