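# actisurv

Composite physical-activity / sedentary-behaviour (PA/SB) scores that
predict all-cause mortality in older adults, from wrist-accelerometer
epochs to externally validated survival performance.

## The problem

Wrist accelerometry characterises daily movement behaviour along many more
dimensions than the "minutes of moderate-to-vigorous activity" that
guidelines target: overall activity level, total time in sedentary
behaviour (SB), light (LIPA) and moderate-to-vigorous (MVPA) activity, how
that time is accumulated into bouts, bout frequency, the intensity
distribution of the day, and the timing of activity. These features are
strongly inter-correlated, so screening them one at a time or with
selection methods that assume independence is unreliable. `actisurv`
implements the full analysis chain for deriving a *single composite score*
from 21 such features that predicts mortality risk, and for quantifying
what that score adds over traditional risk factors:

1. **Feature extraction** (`actisurv.features`) — from 60-s epoch ENMO
   series (mg) with a waking mask: epochs are classified SB (< 40 mg),
   LIPA (40–99 mg) or MVPA (≥ 100 mg); bouts are maximal uninterrupted
   runs; 21 features across six movement dimensions are computed,
   including the intensity intercept/gradient (OLS of log minutes per
   25-mg intensity bin on log bin midpoint) and the start of the most
   active 5 consecutive hours (M5 timing).
2. **Score derivation** (`actisurv.spls`) — sparse partial least squares
   for censored outcomes: deviance residuals `d_i` of the covariate-free
   Nelson–Aalen null model are the working response; each component weight
   is `w ∝ soft_threshold(Xᵀd, η·max|Xᵀd|)`, normalised, with X and the
   residual deflated between components. η ∈ [0,1) and the number of
   components K are tuned by event-stratified cross-validation of
   Harrell's C. Scores are standardised to SD 1 in the derivation cohort,
   so Cox hazard ratios read per SD.
3. **Survival evaluation** (`actisurv.evaluate`) — Cox proportional-hazards
   models (own Newton–Raphson engine, Efron ties), HR per SD, Royston's
   R²_D, AIC, Harrell's C, Youden-optimal sensitivity/specificity,
   bootstrap ΔAIC/ΔC between nested models, restricted-cubic-spline
   nonlinearity tests, subgroup panels and external validation with score
   transfer.
4. **Synthetic cohorts** (`actisurv.simulate`) — a semi-Markov bout
   generator for epoch traces and a Gaussian-copula feature/survival
   generator with known ground truth, emulating an older-adult cohort
   (~32 mg mean acceleration, ~75% of waking time sedentary, ~10% deaths
   over an 8-year horizon), so every stage is testable without restricted
   cohort data.

## Worked example

```python
from actisurv import (default_profile, simulate_epoch_series, extract_cohort,
                      derive_scores)
from actisurv.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="demo", seed=11, n_participants=300,
                     external_n=150, days=3, bootstrap_B=100, folds=4)
report = run_pipeline(cfg)
e = report["stages"]["evaluate"]
print(e["hr_per_sd"]["score_1"])
print(e["comparisons"]["model2_vs_model1"]["delta_c"])
```

prints (seed 11):

```
{'hr': 2.069974595970925, 'ci': [1.6029998121142999, 2.6729852340490927]}
0.1119
```

i.e. in the simulated demo cohort a one-SD increase in composite score 1
roughly doubles the mortality hazard after adjustment for the age-like
and sex-like confounders, and adding the score to the confounder-only
model raises the concordance index by 0.112. (The simulated effect is
deliberately stronger than in real cohorts so small demo runs have power;
`report["stages"]["validate"]` holds the external-cohort analogue.) The
run directory contains the epoch and cohort CSVs, the serialized score
model, per-feature loadings, subgroup tables, an SVG of the score–hazard
spline, and `report.json`/`report.md`.

The same stages are exposed on the command line:

```sh
actisurv simulate --n 200 --days 3 --seed 0 --out epochs.csv
actisurv extract epochs.csv --out features.csv
actisurv run --config config.yaml
```

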