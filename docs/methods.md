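# Methods

## Feature extraction

Input is a per-participant series of 60-s epochs carrying average ENMO
acceleration (mg, non-negative) and a waking flag; non-waking epochs are
excluded from every feature. Epochs are classified by fixed thresholds with
half-open intervals: SB `[0, 40)` mg, LIPA `[40, 100)` mg, MVPA
`[100, ∞)`. A bout is a maximal uninterrupted run of one class within a
day's waking period; a day boundary or a non-waking epoch always terminates
a bout, and no interruption tolerance is applied.

The 21 features and their conventions:

* durations (`dur_SB/LIPA/MVPA`, the SB bout-length classes `[0,10)`,
  `[10,30)`, `[30,∞)` min, and the `<10` / `≥10` min LIPA and MVPA
  classes) and bout counts are computed per day and averaged over retained
  days with equal weight;
* mean bout durations are ratios of sums (total class minutes over total
  bout count across days), which keeps `mean_bout × n_bouts = duration`
  exact at the participant level;
* `days_mvpa30` is the absolute count of recorded days with ≥ 30 min MVPA;
* `mean_acceleration` is the waking-time-weighted mean ENMO across days;
* the intensity intercept/gradient are the OLS intercept and slope of
  `ln(minutes per day in bin)` on `ln(bin midpoint)` over non-empty
  fixed-width 25-mg bins starting at 0 (the dominant binning convention in
  the intensity-distribution literature; the per-day scaling of bin
  minutes shifts only the intercept). At least two non-empty bins are
  required;
* `timing_pa` (M5) is the start clock-hour of the 300-consecutive-epoch
  waking window with maximal summed acceleration, earliest window on ties,
  averaged over days with ≥ 300 waking epochs. Summed acceleration is the
  activity proxy within the window.

`standardize_by_waking` rescales durations and bout counts by
`reference / actual` waking minutes (reference 960 min/day). Ratio-type,
intensity and timing features and the day count with ≥ 30 min MVPA are
left unchanged, so the tiling and mean×count identities survive rescaling.
The minimum-wear / valid-day rule is left to the caller: every day present
in the input with at least one waking epoch is retained.

## Sparse PLS for censored outcomes

The working response is the deviance residual of the covariate-free null
model: with `Λ̂₀` the Nelson–Aalen cumulative hazard, the martingale
residual is `m_i = δ_i − Λ̂₀(t_i)` and

    d_i = sign(m_i) · sqrt(−2·[m_i + δ_i·ln(δ_i − m_i)]),

the `δ_i·ln(·)` term vanishing for censored subjects. Deviance rather than
martingale residuals are used because their near-symmetric distribution
suits a least-squares inner step.

Features are standardised column-wise (SD with `ddof=1`). For component
k = 1..K on the deflated matrix `X_k` and residual `d_k`:

    w_k ∝ soft_threshold(X_kᵀ d_k, λ),  λ = η·max_j |X_kᵀ d_k|_j,
    t_k = X_k w_k,

with `w_k` normalised to unit Euclidean norm; both `X` and the residual
are deflated by regression on `t_k`, which makes the in-sample component
scores exactly orthogonal. `η = 0` reproduces plain PLS; as `η → 1` the
support shrinks monotonically; an empty support raises an explicit
empty-selection condition. New-data scores use the standard rotation
`R = W(PᵀW)^{-1}` so the derivation cohort's stored scores are reproduced
exactly. Scores are standardised to mean 0, SD 1 in the derivation cohort
(per-SD hazard ratios); under `local` standardisation mode both the
features and the resulting scores are re-standardised on the new cohort,
making the transfer invariant to affine feature rescaling — the default
for external validation, where device wear (dominant vs non-dominant
wrist) shifts feature scales. Both the sparse weight vectors and the
feature–score correlation loadings are exported; "selected" features are
the support of the weight vector.

(K, η) are tuned by V-fold cross-validation (default 5 folds) stratified
on the event indicator: per grid cell, the scorer is fit on the training
folds, a Cox model on the training-fold scores supplies component
weights, and the held-out linear predictor is scored by Harrell's C;
the cell maximising the fold-mean C wins, first cell in grid order on
ties. Harrell's C was chosen as the tuning criterion to match the
discrimination focus of the downstream evaluation.

## Cox fitting and performance metrics

The Cox partial likelihood is maximised by Newton–Raphson with step
halving; Efron's tie correction is the default (times recorded at coarse
resolution produce ties; Breslow is available). Convergence requires the
largest absolute score component < 1e-8 (50-iteration cap, error carrying
the gradient norm on failure); a stall within round-off of the optimum
with score < 1e-5 is accepted, which handles near-collinear designs.
Coefficients crossing |β| > 15 raise a separation error — monotone partial
likelihoods flatten as |β| grows, so divergence past any plausible effect
size means the MLE does not exist. Standard errors come from the
pseudo-inverse of the observed information (a zero-information column gets
se 0 rather than a crash). The engine is implemented in-package because
the bootstrap, cross-validation and calibration harnesses refit tens of
thousands of small models; it is cross-checked against an independent
implementation in the test suite.

* **Harrell's C**: pairs `(i, j)` are comparable when `t_i < t_j` and i
  had the event; concordant when `lp_i > lp_j`; tied predictors earn half
  credit.
* **Royston's R²_D**: the predictor is rank-transformed to Blom
  normal-order scores scaled by `κ = √(8/π)`; the Cox coefficient of that
  regressor is the separation statistic D and
  `R²_D = (D²/κ²)/(π²/6 + D²/κ²)`. A constant predictor returns 0 with a
  warning.
* **Youden cutoff**: the classification label is the observed event
  indicator, ignoring censoring time — a documented simplification, since
  no time-horizon ROC convention is imposed; the score scanned is the
  predicted event probability at the end of follow-up (Breslow baseline),
  so cutoffs live on a probability-like scale. All midpoints between
  consecutive unique scores are scanned; smallest maximiser wins.
* **Nested-model comparison**: point ΔAIC/ΔC from full-sample fits;
  percentile 2.5/97.5 CIs from B participant-level bootstrap resamples
  (default 1000) refitting both models per replicate; a CI excluding zero
  is flagged significant. Failed replicates are redrawn and counted;
  more than 10% failures aborts. Callers that operate on very small
  strata (subgroup and external panels) degrade to point deltas with NaN
  CIs and a warning instead of failing the whole run.
* **Nonlinearity**: a restricted cubic spline with 3 knots at the
  10th/50th/90th percentiles adds one basis column; 2Δloglik is referred
  to χ²(1).

## Synthetic data

The epoch generator is an alternating-state semi-Markov process: states
{SB, LIPA, MVPA} never self-transition (so thresholding recovers the
generating state of every epoch exactly), bout lengths are geometric on
the 60-s epoch grid by default (memoryless; lognormal optional), and each
epoch draws an ENMO value from a per-state truncated normal whose support
respects the class thresholds. The default profile targets an older-adult
wrist cohort: ~985 waking minutes/day, ~75% sedentary, SB bouts ~10 min
against ~2.4-min LIPA and MVPA bouts, transition probabilities balanced to
yield ≈ 72/86/23 SB/LIPA/MVPA bouts per day, emission means 14/60/140 mg.
A per-participant latent activity level (lognormal multipliers on bout
means and emission means, scale 0.45) plus waking-duration jitter (SD 40
min) creates correlated between-person variation; the resulting cohort
mean acceleration is ≈ 32–35 mg with SD ≈ 10 mg and intensity gradient
≈ −2.1, on the scale reported for such cohorts. Days per participant is a
free parameter (default 9; demo runs use 3 for speed).

The participant-level generator draws features from a Gaussian copula with
normal marginals (means/SDs from the built-in older-adult reference table)
and a one-factor correlation structure — products of loadings on a latent
activity axis give pairwise |r| ≈ 0.4–0.6 for most features and ≈ 0 for
activity timing. Mortality follows a Weibull (default exponential)
proportional-hazards process: per-SD feature effects act on the
standardized scale, confounders (age-like, sex-like) on the natural scale;
observed time is the minimum of the event time, an optional exponential
censoring time and the administrative horizon (default 8 years, baseline
rate 0.0132/yr ⇒ ≈ 10% events marginally). The generator records the
active feature set, β, the latent linear predictor and the analytic
marginal event fraction as ground truth.

What the generator does **not** emulate: raw sub-second signals,
autocalibration or non-wear artefacts, sleep-detection error, skewed or
heavy-tailed feature marginals, non-proportional hazards, and informative
censoring. Passing tests therefore demonstrate correctness of the
algorithms and calibration of the inference under a well-specified PH
world, not robustness to those real-data pathologies.

## Pipeline and problem sizes

`run_pipeline` executes simulate → extract → derive → evaluate → validate
from one config; all randomness descends from a single seed through
spawned child seeds, every intermediate artifact is written to disk
(epoch/cohort CSVs, score-model JSON, loading/subgroup tables, report
JSON/Markdown), and a rerun under the same config is byte-identical. In
the derivation cohort mortality is simulated from the *extracted*
features (per-SD effects on five of them, defaults in
`pipeline.DEFAULT_BETA`) plus confounders, so the selection stage has a
known target. Subgroup panels skip strata with fewer than
`subgroup_min_events` (default 10) deaths.

Default sizes were chosen so the demo and the acceptance script finish in
minutes on one core while keeping the statistical checks well-powered:
demo cohorts of a few hundred participants × 3 days, B = 100–200
bootstrap replicates, recovery sweeps with n = 2000 × 21 features,
coverage sweeps with 200–500 replicates at n = 4000. The simulated
per-SD effects in the demo are larger than those reported in real
cohorts (HR per SD ≈ 1.5 vs ≈ 1.1) precisely because the demo n is
hundreds rather than thousands; the calibration sweeps use the realistic
HR = 1.10 at n = 4000.

## Known limitations

* The sparse-PLS variant implemented (soft-thresholded covariance
  direction, double deflation, C-tuned) is stated explicitly rather than
  claimed equivalent to any particular published variant; loadings are
  exported both as weights and as correlations so either reading is
  available.
* Sensitivity/specificity under censoring use the observed-event label;
  with heavy censoring they underestimate cumulative incidence at the
  horizon.
* No competing risks, time-varying effects or calibration-curve
  assessment; discrimination and fit only.
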