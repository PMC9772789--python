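"""Survival prediction-performance evaluation: model panels, nested-model
bootstrap comparison, nonlinearity testing, subgroup and external validation.

The evaluation mirrors a three-model design: Model 1 holds the traditional
risk factors, Model 2 adds composite score 1, Model 3 further adds composite
score 2. Performance is summarized by Royston's R^2_D, AIC, Harrell's C and
the Youden-optimal sensitivity/specificity; added value of a score is the
bootstrap-interval change in AIC and C against the nested reference model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import CoxPH, _as_time_event, fit_cox
from .metrics import harrell_c, royston_r2d, youden_cutoff
from .spls import SparsePLSCoxScorer, apply_score

__all__ = [
    "fit_cox", "harrell_c", "royston_r2d", "youden_cutoff",
    "hazard_ratio_per_sd", "performance_panel", "compare_nested_models",
    "spline_nonlinearity_test", "subgroup_analysis", "external_validation",
    "rcs_basis", "PerformancePanel", "ComparisonResult",
]


def hazard_ratio_per_sd(fit: CoxPH, feature: str) -> tuple[float, tuple]:
    """HR and Wald 95% CI per SD of a pre-standardized feature."""
    j = fit.feature_names_.index(feature)
    if abs(fit.col_sd_[j] - 1.0) > 1e-6:
        raise ValueError(
            f"feature {feature!r} is not standardized to SD 1 "
            f"(SD = {fit.col_sd_[j]:.6f}); standardize before fitting")
    b, se = fit.coef_[j], fit.se_[j]
    return float(np.exp(b)), (float(np.exp(b - 1.96 * se)),
                              float(np.exp(b + 1.96 * se)))


@dataclass
class PerformancePanel:
    r2d: float
    aic: float
    c_index: float
    youden_cutoff: float
    sensitivity: float
    specificity: float
    c_ci: tuple | None = None

    def to_dict(self) -> dict:
        out = {"r2d": self.r2d, "aic": self.aic, "c_index": self.c_index,
               "youden_cutoff": self.youden_cutoff,
               "sensitivity_pct": self.sensitivity,
               "specificity_pct": self.specificity}
        if self.c_ci is not None:
            out["c_index_ci"] = list(self.c_ci)
        return out


def performance_panel(records: pd.DataFrame, design_cols: list[str],
                      ties: str = "efron", B: int = 0,
                      seed: int = 0) -> PerformancePanel:
    """Full performance panel for one Cox design.

    The classification score for the Youden cutoff is the predicted event
    probability by the end of follow-up (Breslow baseline), so cutoffs are
    on a probability-like scale; C and R^2_D use the linear predictor.
    Optional ``B`` bootstrap replicates give a percentile CI for C.
    """
    fit = fit_cox(records, design_cols, ties=ties)
    lp = fit.linear_predictor_
    t, _ = _as_time_event(records)
    risk = fit.predict_risk(records[design_cols], float(t.max()))
    cut, sens, spec = youden_cutoff(risk, records)
    c_ci = None
    if B > 0:
        rng = np.random.default_rng(seed)
        n = len(records)
        cs = []
        while len(cs) < B:
            idx = rng.integers(0, n, n)
            sub = records.iloc[idx]
            try:
                f = fit_cox(sub, design_cols, ties=ties)
                cs.append(harrell_c(f.linear_predictor_, sub))
            except (ValueError, RuntimeError):
                continue
        c_ci = tuple(np.percentile(cs, [2.5, 97.5]))
    return PerformancePanel(
        r2d=royston_r2d(lp, records, ties=ties), aic=fit.aic_,
        c_index=harrell_c(lp, records), youden_cutoff=cut,
        sensitivity=sens, specificity=spec, c_ci=c_ci)


@dataclass
class ComparisonResult:
    delta_aic: float
    delta_c: float
    ci_aic: tuple
    ci_c: tuple
    B: int
    n_failures: int = 0
    significant_aic: bool = field(init=False)
    significant_c: bool = field(init=False)

    def __post_init__(self) -> None:
        def excludes_zero(ci):
            if np.isnan(ci[0]) or np.isnan(ci[1]):
                return False
            return not (ci[0] <= 0.0 <= ci[1])

        self.significant_aic = excludes_zero(self.ci_aic)
        self.significant_c = excludes_zero(self.ci_c)

    def to_dict(self) -> dict:
        return {"delta_aic": self.delta_aic, "delta_c": self.delta_c,
                "ci_aic": list(self.ci_aic), "ci_c": list(self.ci_c),
                "B": self.B, "n_failures": self.n_failures,
                "significant_aic": self.significant_aic,
                "significant_c": self.significant_c}


def _fit_deltas(records, design_ref, design_aug, ties):
    ref = fit_cox(records, design_ref, ties=ties)
    aug = fit_cox(records, design_aug, ties=ties)
    d_aic = aug.aic_ - ref.aic_
    d_c = (harrell_c(aug.linear_predictor_, records)
           - harrell_c(ref.linear_predictor_, records))
    return d_aic, d_c


def compare_nested_models(records: pd.DataFrame, design_ref: list[str],
                          design_aug: list[str], B: int = 1000,
                          seed: int = 0, ties: str = "efron"
                          ) -> ComparisonResult:
    """Added predictive value of the augmented over the reference design.

    Point deltas (AIC, C) come from the full sample; percentile 2.5/97.5
    CIs from ``B`` participant-level bootstrap resamples, each refitting
    both models. A CI excluding zero is flagged significant. Replicates
    whose fits fail are redrawn; more than 10% failures aborts.
    """
    if not set(design_ref) <= set(design_aug):
        raise ValueError("reference design must be nested in the augmented "
                         "design")
    d_aic, d_c = _fit_deltas(records, design_ref, design_aug, ties)
    rng = np.random.default_rng(seed)
    n = len(records)
    aics, cs = [], []
    failures = 0
    while len(aics) < B:
        idx = rng.integers(0, n, n)
        sub = records.iloc[idx].reset_index(drop=True)
        try:
            da, dc = _fit_deltas(sub, design_ref, design_aug, ties)
        except (ValueError, RuntimeError):
            failures += 1
            if failures > max(0.1 * B, 1):
                raise RuntimeError(
                    f"more than 10% of bootstrap replicates failed "
                    f"({failures} failures)")
            continue
        aics.append(da)
        cs.append(dc)
    return ComparisonResult(
        delta_aic=d_aic, delta_c=d_c,
        ci_aic=tuple(np.percentile(aics, [2.5, 97.5])),
        ci_c=tuple(np.percentile(cs, [2.5, 97.5])),
        B=B, n_failures=failures)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline nonlinear basis columns.

    For k knots, returns k-2 columns; the function is linear beyond the
    outer knots. Knots must be strictly increasing.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"knots must be distinct and increasing: {knots}")
    k = knots.size
    kn_last, kn_pen = knots[-1], knots[-2]
    norm = (kn_last - knots[0]) ** 2

    def d3(a):
        return np.maximum(x - a, 0.0) ** 3

    cols = []
    for j in range(k - 2):
        term = (d3(knots[j])
                - d3(kn_pen) * (kn_last - knots[j]) / (kn_last - kn_pen)
                + d3(kn_last) * (kn_pen - knots[j]) / (kn_last - kn_pen))
        cols.append(term / norm)
    return np.column_stack(cols)


def spline_nonlinearity_test(records: pd.DataFrame, score_col: str,
                             covariate_cols: list[str] | None = None,
                             ties: str = "efron") -> tuple[float, float]:
    """Likelihood-ratio test of nonlinearity for a continuous score.

    A restricted cubic spline with 3 knots at the 10th/50th/90th score
    percentiles adds one basis column to the linear model; the LRT statistic
    2*(loglik_spline - loglik_linear) is referred to chi-square with df
    equal to the added columns. Returns (p_value, statistic).
    """
    from scipy.stats import chi2

    covariate_cols = list(covariate_cols or [])
    x = records[score_col].to_numpy(dtype=float)
    knots = np.percentile(x, [10, 50, 90])
    if np.unique(knots).size < 3:
        raise ValueError(f"duplicate spline knots {knots}; score variance "
                         "too low")
    basis = rcs_basis(x, knots)
    lin = fit_cox(records, covariate_cols + [score_col], ties=ties)
    aug = records.copy()
    spline_cols = []
    for j in range(basis.shape[1]):
        col = f"_rcs_{score_col}_{j}"
        aug[col] = basis[:, j]
        spline_cols.append(col)
    spl = fit_cox(aug, covariate_cols + [score_col] + spline_cols, ties=ties)
    stat = max(2.0 * (spl.loglik_ - lin.loglik_), 0.0)
    p = float(chi2.sf(stat, df=len(spline_cols))) if stat > 0 else 1.0
    return p, float(stat)


def subgroup_analysis(records: pd.DataFrame, score_col: str,
                      covariate_cols: list[str], group_col: str,
                      B: int = 200, seed: int = 0, min_events: int = 1,
                      ties: str = "efron") -> pd.DataFrame:
    """Per-stratum association and added value of the composite score.

    Within each level of ``group_col`` the reference model (covariates) and
    the augmented model (covariates + score) are refit and compared; strata
    with fewer than ``min_events`` events are skipped with a warning (the
    bootstrap is unstable when a stratum carries almost no deaths). The HR
    is per derivation-SD of the score (the score column is assumed already
    standardized in the derivation cohort).
    """
    rows = []
    for level, sub in records.groupby(group_col, sort=True, observed=True):
        sub = sub.reset_index(drop=True)
        if sub["event"].sum() < max(min_events, 1):
            warnings.warn(f"stratum {group_col}={level!r} has fewer than "
                          f"{max(min_events, 1)} events; skipped",
                          stacklevel=2)
            continue
        design_ref = [c for c in covariate_cols if sub[c].nunique() > 1]
        aug_fit = fit_cox(sub, design_ref + [score_col], ties=ties)
        ci = aug_fit.confidence_intervals().loc[score_col]
        try:
            cmp_res = compare_nested_models(sub, design_ref,
                                            design_ref + [score_col],
                                            B=B, seed=seed, ties=ties)
            delta_c, (c_lo, c_hi) = cmp_res.delta_c, cmp_res.ci_c
            significant = cmp_res.significant_c
        except RuntimeError as err:
            warnings.warn(f"bootstrap unstable in stratum "
                          f"{group_col}={level!r}: {err}", stacklevel=2)
            delta_c, c_lo, c_hi = _fit_deltas(
                sub, design_ref, design_ref + [score_col], ties)[1], \
                float("nan"), float("nan")
            significant = False
        rows.append({
            "group": f"{group_col}={level}", "n": len(sub),
            "n_events": int(sub["event"].sum()),
            "hr": float(np.exp(ci["coef"])),
            "hr_lo": float(np.exp(ci["lower"])),
            "hr_hi": float(np.exp(ci["upper"])),
            "delta_c": delta_c,
            "delta_c_lo": c_lo, "delta_c_hi": c_hi,
            "significant": significant,
        })
    return pd.DataFrame(rows)


def external_validation(model: SparsePLSCoxScorer,
                        external_features: pd.DataFrame,
                        external_records: pd.DataFrame,
                        covariate_cols: list[str],
                        standardization: str = "local",
                        B: int = 1000, seed: int = 0,
                        ties: str = "efron") -> dict:
    """Score transfer and added-value panel on an independent cohort.

    The stored model's weights are applied to the external feature table
    (local feature standardization by default, appropriate when device
    placement differs), then Model 1 (covariates) and Model 2 (covariates +
    composite score 1) are fit and compared on the external cohort only.
    """
    scores = apply_score(model, external_features,
                         standardization=standardization)
    rec = external_records.reset_index(drop=True).copy()
    rec["score_1"] = scores["score_1"].to_numpy()
    m1 = performance_panel(rec, covariate_cols, ties=ties)
    m2 = performance_panel(rec, covariate_cols + ["score_1"], ties=ties)
    try:
        comparison = compare_nested_models(rec, covariate_cols,
                                           covariate_cols + ["score_1"],
                                           B=B, seed=seed, ties=ties)
    except RuntimeError as err:
        # very small validation cohorts: report point deltas without CIs
        warnings.warn(f"external bootstrap unstable: {err}", stacklevel=2)
        da, dc = _fit_deltas(rec, covariate_cols,
                             covariate_cols + ["score_1"], ties)
        comparison = ComparisonResult(delta_aic=da, delta_c=dc,
                                      ci_aic=(float("nan"), float("nan")),
                                      ci_c=(float("nan"), float("nan")),
                                      B=0)
    fit2 = fit_cox(rec, covariate_cols + ["score_1"], ties=ties)
    ci = fit2.confidence_intervals().loc["score_1"]
    return {
        "hr": float(np.exp(ci["coef"])),
        "hr_ci": [float(np.exp(ci["lower"])), float(np.exp(ci["upper"]))],
        "model1": m1.to_dict(),
        "model2": m2.to_dict(),
        "comparison": comparison.to_dict(),
    }


def plot_spline_association(records: pd.DataFrame, score_col: str,
                            covariate_cols: list[str], path,
                            ties: str = "efron") -> None:
    """Log-HR versus score: linear term and restricted-cubic-spline fit."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = records[score_col].to_numpy(dtype=float)
    knots = np.percentile(x, [10, 50, 90])
    lin = fit_cox(records, list(covariate_cols) + [score_col], ties=ties)
    aug = records.copy()
    basis = rcs_basis(x, knots)
    aug["_rcs0"] = basis[:, 0]
    spl = fit_cox(aug, list(covariate_cols) + [score_col, "_rcs0"], ties=ties)
    grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), 100)
    b_lin = lin.coef_[lin.feature_names_.index(score_col)]
    b_s1 = spl.coef_[spl.feature_names_.index(score_col)]
    b_s2 = spl.coef_[spl.feature_names_.index("_rcs0")]
    gb = rcs_basis(grid, knots)[:, 0]
    ref = float(np.median(x))
    ref_b = rcs_basis(np.array([ref]), knots)[0, 0]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(grid, b_lin * (grid - ref), label="linear", color="black")
    ax.plot(grid, b_s1 * (grid - ref) + b_s2 * (gb - ref_b),
            label="cubic spline", color="tab:blue", ls="--")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel(score_col)
    ax.set_ylabel("log hazard ratio")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
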