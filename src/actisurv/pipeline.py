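"""End-to-end orchestration: simulate -> extract -> derive-score ->
evaluate -> validate, from a single config, with on-disk artifacts at every
stage and a machine-readable report.

The derivation cohort is built from simulated epoch traces: features are
extracted from the epochs, mortality is then simulated from a proportional-
hazards process whose linear predictor loads on a configured subset of the
extracted (standardized) features plus confounders — so the ground truth the
score-derivation stage should recover is known and recorded. The external
cohort repeats the process with an independent seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import features as feat
from . import simulate as sim
from .spls import SparsePLSCoxScorer, derive_scores

log = logging.getLogger("actisurv")

STAGES = ("simulate", "extract", "derive", "evaluate", "validate")

DEFAULT_BETA = {
    "mean_acceleration": -0.22,
    "dur_MVPA": -0.18,
    "sb_ge30": 0.16,
    "mean_bout_SB": 0.12,
    "intensity_gradient": -0.16,
}


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run; every number in the report is a
    function of this config alone."""

    outdir: str = "actisurv_run"
    seed: int = 1
    n_participants: int = 500
    external_n: int = 250
    days: int = 3
    waking_minutes: float = 985.0
    sb_threshold: float = 40.0
    mvpa_threshold: float = 100.0
    bin_width: float = 25.0
    standardize_waking: bool = False
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    baseline_rate: float = 0.0132
    horizon_years: float = 8.0
    censoring_rate: float = 0.0
    k_grid: tuple = (1, 2)
    eta_grid: tuple = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))
    folds: int = 5
    bootstrap_B: int = 200
    subgroups: tuple = ("age_band", "female")
    subgroup_min_events: int = 10
    external_standardization: str = "local"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    model_json: str | None = None
    write_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_canonical_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["k_grid"] = list(self.k_grid)
        d["eta_grid"] = [float(e) for e in self.eta_grid]
        d["subgroups"] = list(self.subgroups)
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_yaml().encode()).hexdigest()[:16]

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        on = {s: self.stages.get(s, True) for s in STAGES}
        if on["extract"] and not on["simulate"]:
            if not (Path(self.outdir) / "epochs.csv").exists():
                raise ValueError("extract enabled without simulate stage and "
                                 "no epochs.csv present")
        if on["derive"] and not on["extract"]:
            if not (Path(self.outdir) / "cohort.csv").exists():
                raise ValueError("derive enabled without extract stage and "
                                 "no cohort.csv present")
        if on["evaluate"] and not on["derive"] and self.model_json is None:
            raise ValueError("evaluation enabled but no score stage and no "
                             "score model file configured")


def _child_seeds(seed: int, n: int = 10) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _simulate_stage(cfg: PipelineConfig, outdir: Path, seeds: list[int]) -> dict:
    profile = sim.default_profile(days=cfg.days,
                                  waking_minutes=cfg.waking_minutes)
    epochs = sim.simulate_epoch_series(profile, cfg.n_participants, seeds[0])
    sim.write_epoch_csv(epochs, outdir / "epochs.csv")
    ext = sim.simulate_epoch_series(profile, cfg.external_n, seeds[1],
                                    participant_offset=10_000_000)
    sim.write_epoch_csv(ext, outdir / "epochs_external.csv")
    return {"n_participants": cfg.n_participants,
            "external_n": cfg.external_n, "days": cfg.days,
            "epoch_rows": int(len(epochs))}


def _build_cohort(cfg: PipelineConfig, epochs: pd.DataFrame,
                  survival_seed: int, covariate_seed: int
                  ) -> tuple[pd.DataFrame, dict]:
    features = feat.extract_cohort(epochs, sb_threshold=cfg.sb_threshold,
                                   mvpa_threshold=cfg.mvpa_threshold,
                                   bin_width=cfg.bin_width)
    if cfg.standardize_waking:
        features = feat.standardize_cohort_by_waking(features)
    fcols = list(sim.FEATURE_NAMES)
    z = (features[fcols] - features[fcols].mean()) / features[fcols].std(ddof=1)
    beta_vec = np.array([cfg.beta.get(f, 0.0) for f in fcols])
    lp = z.to_numpy() @ beta_vec
    rng = np.random.default_rng(covariate_seed)
    cohort = features.reset_index()
    for cov in sim.default_covariates():
        x = cov.sample(rng, len(cohort))
        cohort[cov.name] = x
        lp = lp + cov.beta * (x - x.mean())
    spec = sim.CohortSpec(n=len(cohort), baseline_rate=cfg.baseline_rate,
                          horizon_years=cfg.horizon_years,
                          censoring_rate=cfg.censoring_rate,
                          seed=survival_seed)
    surv = sim.simulate_survival(lp, spec, seed=survival_seed)
    cohort = pd.concat([cohort, surv], axis=1)
    cohort["age_band"] = np.where(cohort["age"] < 74, "<74", ">=74")
    truth = {
        "beta": {k: v for k, v in cfg.beta.items() if v != 0.0},
        "support": sorted(k for k, v in cfg.beta.items() if v != 0.0),
        "event_fraction": float(surv["event"].mean()),
    }
    return cohort, truth


def _extract_stage(cfg: PipelineConfig, outdir: Path, seeds: list[int]) -> dict:
    epochs = sim.read_epoch_csv(outdir / "epochs.csv")
    cohort, truth = _build_cohort(cfg, epochs, seeds[2], seeds[3])
    cohort.to_csv(outdir / "cohort.csv", index=False)
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))

    ext_epochs = sim.read_epoch_csv(outdir / "epochs_external.csv")
    ext_cohort, _ = _build_cohort(cfg, ext_epochs, seeds[4], seeds[5])
    ext_cohort.to_csv(outdir / "cohort_external.csv", index=False)

    fcols = list(sim.FEATURE_NAMES)
    summary = pd.DataFrame({
        "mean": cohort[fcols].mean().round(4),
        "sd": cohort[fcols].std(ddof=1).round(4),
    })
    summary.to_csv(outdir / "feature_summary.csv")
    return {"feature_summary": {k: [float(summary.loc[k, "mean"]),
                                    float(summary.loc[k, "sd"])]
                                for k in fcols},
            "n_events": int(cohort["event"].sum()),
            "event_fraction": float(cohort["event"].mean()),
            "ground_truth": truth}


def _derive_stage(cfg: PipelineConfig, outdir: Path, seeds: list[int]) -> dict:
    cohort = pd.read_csv(outdir / "cohort.csv")
    fcols = list(sim.FEATURE_NAMES)
    scorer = derive_scores(cohort[fcols], cohort, k_grid=tuple(cfg.k_grid),
                           eta_grid=tuple(cfg.eta_grid), folds=cfg.folds,
                           seed=seeds[6])
    (outdir / "spls_model.json").write_text(scorer.to_json())
    scores = scorer.transform(cohort[fcols])
    for k in range(scores.shape[1]):
        cohort[f"score_{k + 1}"] = scores[:, k]
    cohort.to_csv(outdir / "cohort_scored.csv", index=False)
    loadings = pd.DataFrame(
        {"weight_1": scorer.weights_[:, 0],
         "corr_loading_1": scorer.corr_loadings_[:, 0]}, index=fcols)
    if scorer.n_components > 1:
        loadings["weight_2"] = scorer.weights_[:, 1]
        loadings["corr_loading_2"] = scorer.corr_loadings_[:, 1]
    loadings.round(6).to_csv(outdir / "loadings.csv")
    return {"K": int(scorer.n_components), "eta": float(scorer.eta),
            "selected": [list(s) for s in scorer.selected_],
            "cv_best_c": float(scorer.cv_trace_["cv_c"].max()),
            "loadings": {c: loadings[c].round(4).to_dict()
                         for c in loadings.columns}}


def _evaluate_stage(cfg: PipelineConfig, outdir: Path, seeds: list[int]) -> dict:
    cohort = pd.read_csv(outdir / "cohort_scored.csv")
    covs = ["age", "female"]
    score_cols = [c for c in ("score_1", "score_2") if c in cohort.columns]
    designs = {"model1": covs}
    designs["model2"] = covs + ["score_1"]
    if "score_2" in score_cols:
        designs["model3"] = covs + ["score_1", "score_2"]
    B = cfg.bootstrap_B
    out: dict = {"panels": {}, "comparisons": {}, "hr_per_sd": {}}
    for name, design in designs.items():
        out["panels"][name] = ev.performance_panel(
            cohort, design, B=0).to_dict()
    fit_full = ev.fit_cox(cohort, designs[max(designs)], ties="efron")
    for s in score_cols:
        hr, ci = ev.hazard_ratio_per_sd(fit_full, s)
        out["hr_per_sd"][s] = {"hr": hr, "ci": list(ci)}
        p_nl, stat = ev.spline_nonlinearity_test(cohort, s, covs)
        out.setdefault("nonlinearity_p", {})[s] = p_nl
    out["comparisons"]["model2_vs_model1"] = ev.compare_nested_models(
        cohort, designs["model1"], designs["model2"], B=B,
        seed=seeds[7]).to_dict()
    if "model3" in designs:
        out["comparisons"]["model3_vs_model2"] = ev.compare_nested_models(
            cohort, designs["model2"], designs["model3"], B=B,
            seed=seeds[7]).to_dict()
    sub_frames = []
    for g in cfg.subgroups:
        sub_frames.append(ev.subgroup_analysis(
            cohort, "score_1", covs, g, B=max(B // 2, 50),
            min_events=cfg.subgroup_min_events, seed=seeds[8]))
    subgroups = pd.concat(sub_frames, ignore_index=True)
    subgroups.to_csv(outdir / "subgroups.csv", index=False)
    out["subgroups"] = subgroups.round(6).to_dict(orient="records")
    if cfg.write_figures:
        ev.plot_spline_association(cohort, "score_1", covs,
                                   outdir / "score1_spline.svg")
    return out


def _validate_stage(cfg: PipelineConfig, outdir: Path, seeds: list[int]) -> dict:
    ext = pd.read_csv(outdir / "cohort_external.csv")
    model = SparsePLSCoxScorer.from_json(
        (Path(cfg.model_json) if cfg.model_json
         else outdir / "spls_model.json").read_text())
    fcols = list(sim.FEATURE_NAMES)
    return ev.external_validation(
        model, ext[fcols], ext, ["age", "female"],
        standardization=cfg.external_standardization,
        B=cfg.bootstrap_B, seed=seeds[9])


_STAGE_FUNCS = {
    "simulate": _simulate_stage,
    "extract": _extract_stage,
    "derive": _derive_stage,
    "evaluate": _evaluate_stage,
    "validate": _validate_stage,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute enabled stages in order; returns (and writes) the report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(cfg.seed, 10)
    report: dict = {
        "config": yaml.safe_load(cfg.to_canonical_yaml()),
        "config_hash": cfg.config_hash(),
        "seeds": seeds,
        "stages": {},
    }
    for stage in STAGES:
        if not cfg.stages.get(stage, True):
            continue
        t0 = _time.perf_counter()
        log.info("stage %s ...", stage)
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](cfg, outdir, seeds)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        log.info("stage %s done in %.1fs", stage, _time.perf_counter() - t0)
    report_json = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(report_json)
    (outdir / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# actisurv run report", "",
             f"config hash: `{report['config_hash']}`", ""]
    st = report["stages"]
    if "extract" in st:
        lines += ["## Cohort feature summary (mean, SD)", ""]
        for k, (m, s) in st["extract"]["feature_summary"].items():
            lines.append(f"- {k}: {m:.2f} ({s:.2f})")
        lines += ["", f"events: {st['extract']['n_events']} "
                  f"({100 * st['extract']['event_fraction']:.1f}%)", ""]
    if "derive" in st:
        d = st["derive"]
        lines += ["## Composite scores", "",
                  f"K = {d['K']}, eta = {d['eta']}, "
                  f"CV C = {d['cv_best_c']:.3f}",
                  f"selected (score 1): {', '.join(d['selected'][0])}", ""]
    if "evaluate" in st:
        e = st["evaluate"]
        lines += ["## Internal validation", ""]
        for name, panel in e["panels"].items():
            lines.append(
                f"- {name}: C = {panel['c_index']:.3f}, "
                f"AIC = {panel['aic']:.1f}, R2_D = {panel['r2d']:.3f}, "
                f"sens = {panel['sensitivity_pct']:.1f}%, "
                f"spec = {panel['specificity_pct']:.1f}%")
        for name, cmp_d in e["comparisons"].items():
            lines.append(
                f"- {name}: dC = {cmp_d['delta_c']:.4f} "
                f"[{cmp_d['ci_c'][0]:.4f}, {cmp_d['ci_c'][1]:.4f}], "
                f"dAIC = {cmp_d['delta_aic']:.1f}")
        for s, hr in e["hr_per_sd"].items():
            lines.append(f"- HR per SD ({s}): {hr['hr']:.3f} "
                         f"[{hr['ci'][0]:.3f}, {hr['ci'][1]:.3f}]")
        lines.append("")
    if "validate" in st:
        v = st["validate"]
        lines += ["## External validation", "",
                  f"HR per SD: {v['hr']:.3f} "
                  f"[{v['hr_ci'][0]:.3f}, {v['hr_ci'][1]:.3f}]",
                  f"dC = {v['comparison']['delta_c']:.4f} "
                  f"[{v['comparison']['ci_c'][0]:.4f}, "
                  f"{v['comparison']['ci_c'][1]:.4f}]", ""]
    return "\n".join(lines)
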