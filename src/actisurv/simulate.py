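"""Synthetic accelerometer and survival cohorts with known ground truth.

Two generation paths mirror the two input layers of the analysis:

* :func:`simulate_epoch_series` emits 60-s epoch traces (ENMO in mg with a
  waking mask) from an alternating-state semi-Markov bout process, so the
  feature-extraction layer can be exercised end to end;
* :func:`simulate_feature_cohort` + :func:`simulate_survival` emit a
  participant-level feature table with a controlled correlation structure and
  a proportional-hazards mortality outcome, so score derivation and the
  survival evaluation harness can be tested against a known active feature
  set and known per-SD log hazard ratios.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so every artifact is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import simpson

STATES = ("SB", "LIPA", "MVPA")
#: intensity class supports in mg: SB [0,40), LIPA [40,100), MVPA [100,inf)
SB_THRESHOLD = 40.0
MVPA_THRESHOLD = 100.0

#: canonical names of the 21 movement-behaviour features
FEATURE_NAMES = (
    "mean_acceleration",
    "dur_SB", "dur_LIPA", "dur_MVPA",
    "mean_bout_SB", "mean_bout_LIPA", "mean_bout_MVPA",
    "sb_lt10", "sb_10_30", "sb_ge30",
    "lipa_lt10", "lipa_ge10", "mvpa_lt10", "mvpa_ge10",
    "n_bouts_SB", "n_bouts_LIPA", "n_bouts_MVPA",
    "days_mvpa30",
    "intensity_intercept", "intensity_gradient",
    "timing_pa",
)

#: reference marginal means / SDs used by the feature-table generator,
#: on the scale of an older-adult wrist-accelerometer cohort.
FEATURE_STATS = {
    "mean_acceleration": (31.8, 9.7),
    "dur_SB": (717.9, 100.1),
    "dur_LIPA": (210.3, 69.1),
    "dur_MVPA": (56.1, 38.5),
    "mean_bout_SB": (11.5, 5.9),
    "mean_bout_LIPA": (2.4, 0.4),
    "mean_bout_MVPA": (2.3, 0.9),
    "sb_lt10": (147.1, 41.0),
    "sb_10_30": (185.7, 45.3),
    "sb_ge30": (385.0, 143.0),
    "lipa_lt10": (184.0, 54.1),
    "lipa_ge10": (26.4, 21.3),
    "mvpa_lt10": (43.4, 27.6),
    "mvpa_ge10": (12.7, 17.2),
    "n_bouts_SB": (71.8, 16.0),
    "n_bouts_LIPA": (86.0, 21.6),
    "n_bouts_MVPA": (23.2, 13.6),
    "days_mvpa30": (4.5, 2.5),
    "intensity_intercept": (12.4, 0.7),
    "intensity_gradient": (-2.08, 0.22),
    "timing_pa": (10.2, 1.6),
}

#: one-factor loadings on a latent "overall activity" axis; pairwise feature
#: correlation is the product of loadings (|r| ~ 0.4-0.6 between most
#: features, near zero for activity timing, as seen in wrist cohorts).
_FACTOR_LOADINGS = {
    "mean_acceleration": 0.85,
    "dur_SB": -0.70, "dur_LIPA": 0.65, "dur_MVPA": 0.80,
    "mean_bout_SB": -0.60, "mean_bout_LIPA": 0.30, "mean_bout_MVPA": 0.45,
    "sb_lt10": 0.50, "sb_10_30": 0.35, "sb_ge30": -0.70,
    "lipa_lt10": 0.65, "lipa_ge10": 0.40, "mvpa_lt10": 0.75,
    "mvpa_ge10": 0.55,
    "n_bouts_SB": 0.45, "n_bouts_LIPA": 0.55, "n_bouts_MVPA": 0.75,
    "days_mvpa30": 0.70,
    "intensity_intercept": -0.55, "intensity_gradient": 0.70,
    "timing_pa": 0.03,
}

_STATE_BOUNDS = {
    "SB": (0.0, SB_THRESHOLD),
    "LIPA": (SB_THRESHOLD, MVPA_THRESHOLD),
    "MVPA": (MVPA_THRESHOLD, None),
}


class SimulationError(ValueError):
    """Invalid simulation specification."""


@dataclass
class BoutDistribution:
    """Bout length distribution in whole 60-s epochs (>= 1).

    ``geometric`` is memoryless on the epoch grid; ``lognormal`` produces
    heavier-tailed bouts with the same mean.
    """

    mean_minutes: float
    kind: str = "geometric"
    sigma: float = 0.75

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_minutes) or self.mean_minutes <= 0:
            raise SimulationError(
                f"bout mean must be positive and finite, got {self.mean_minutes}")
        if self.kind not in ("geometric", "lognormal"):
            raise SimulationError(f"unknown bout distribution kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, size: int,
               mean_scale: float = 1.0) -> np.ndarray:
        mean = max(self.mean_minutes * mean_scale, 1.0)
        if self.kind == "geometric":
            return rng.geometric(1.0 / mean, size=size)
        mu = np.log(mean) - 0.5 * self.sigma ** 2
        draws = np.rint(rng.lognormal(mu, self.sigma, size=size))
        return np.maximum(draws, 1.0).astype(np.int64)


@dataclass
class EmissionDistribution:
    """Per-epoch ENMO draw (mg): normal truncated to the class support."""

    mean_mg: float
    sd_mg: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd_mg <= 0:
            raise SimulationError("emission SD must be positive")
        if not (self.lower <= self.mean_mg < self.upper):
            raise SimulationError(
                f"emission mean {self.mean_mg} outside support "
                f"[{self.lower}, {self.upper})")

    def sample(self, rng: np.random.Generator, size: int,
               mean_scale: float = 1.0) -> np.ndarray:
        loc = float(np.clip(self.mean_mg * mean_scale,
                            self.lower, self.upper - 1e-6))
        a = (self.lower - loc) / self.sd_mg
        # shave the upper edge so supports stay half-open under thresholding
        b = (self.upper - 1e-9 - loc) / self.sd_mg
        return stats.truncnorm.rvs(a, b, loc=loc, scale=self.sd_mg,
                                   size=size, random_state=rng)


def _check_emission_support(state: str, em: EmissionDistribution) -> None:
    lo, hi = _STATE_BOUNDS[state]
    if em.lower < lo or (hi is not None and em.upper > hi):
        raise SimulationError(
            f"{state} emission support [{em.lower}, {em.upper}) violates the "
            f"class interval [{lo}, {hi})")


@dataclass
class ActivityProfile:
    """Generating model for one stratum of participants.

    Waking time is tiled by an alternating-state semi-Markov sequence of
    bouts: states never self-transition (so thresholding epochs recovers
    bouts exactly), bout lengths come from per-state distributions, and each
    epoch draws an intensity from its state's emission distribution.
    ``between_sd`` adds a per-participant latent activity level that scales
    bout means and emission means, creating realistic correlated
    between-person variation.
    """

    states: tuple[str, ...] = STATES
    bout_dist: dict[str, BoutDistribution] = field(default_factory=dict)
    emission: dict[str, EmissionDistribution] = field(default_factory=dict)
    transition: dict[str, dict[str, float]] = field(default_factory=dict)
    waking_minutes: float = 985.0
    waking_sd_minutes: float = 40.0
    days: int = 9
    waking_start_hour: float = 7.0
    between_sd: float = 0.45
    mvpa_max_mg: float = 500.0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise SimulationError("days per participant must be >= 1")
        if self.waking_minutes < 1:
            raise SimulationError("waking period must cover at least one epoch")
        unknown = set(self.states) - set(STATES)
        if unknown:
            raise SimulationError(f"unknown states {unknown}")
        for s in self.states:
            if s not in self.bout_dist:
                raise SimulationError(f"missing bout distribution for {s}")
            if s not in self.emission:
                raise SimulationError(f"missing emission distribution for {s}")
            _check_emission_support(s, self.emission[s])
        if len(self.states) > 1:
            for s in self.states:
                row = self.transition.get(s)
                if row is None:
                    raise SimulationError(f"missing transition row for {s}")
                if row.get(s, 0.0) != 0.0:
                    raise SimulationError(f"self-transition forbidden ({s})")
                tot = sum(row.get(t, 0.0) for t in self.states)
                if not np.isclose(tot, 1.0):
                    raise SimulationError(
                        f"transition row for {s} sums to {tot}, expected 1")


def default_profile(**overrides) -> ActivityProfile:
    """Older-adult wrist-accelerometer profile.

    Calibrated so the extracted cohort features land on the scale of a
    mostly sedentary 60-83 year old population: ~75% of a ~16.4 h waking
    period sedentary, short light/moderate bouts, cohort mean acceleration
    near 32 mg.
    """
    params = dict(
        bout_dist={
            "SB": BoutDistribution(10.0),
            "LIPA": BoutDistribution(2.4),
            "MVPA": BoutDistribution(2.3),
        },
        emission={
            "SB": EmissionDistribution(14.0, 9.0, 0.0, SB_THRESHOLD),
            "LIPA": EmissionDistribution(60.0, 14.0, SB_THRESHOLD,
                                         MVPA_THRESHOLD),
            "MVPA": EmissionDistribution(140.0, 45.0, MVPA_THRESHOLD, 500.0),
        },
        transition={
            "SB": {"SB": 0.0, "LIPA": 0.944, "MVPA": 0.056},
            "LIPA": {"SB": 0.779, "LIPA": 0.0, "MVPA": 0.221},
            "MVPA": {"SB": 0.217, "LIPA": 0.783, "MVPA": 0.0},
        },
    )
    params.update(overrides)
    return ActivityProfile(**params)


# per-participant latent activity level z scales these, exp(coef * z * between_sd)
_BOUT_RE_COEF = {"SB": -0.8, "LIPA": 0.35, "MVPA": 1.0}
_EMIT_RE_COEF = {"SB": 0.25, "LIPA": 0.10, "MVPA": 0.30}


def _sample_state_sequence(rng: np.random.Generator, states: tuple[str, ...],
                           trans: np.ndarray, start_p: np.ndarray,
                           n_bouts: int) -> np.ndarray:
    """Indices of an alternating-state chain of length n_bouts."""
    cum = np.cumsum(trans, axis=1)
    u = rng.random(n_bouts)
    seq = np.empty(n_bouts, dtype=np.int64)
    seq[0] = np.searchsorted(np.cumsum(start_p), u[0], side="right")
    for i in range(1, n_bouts):
        seq[i] = np.searchsorted(cum[seq[i - 1]], u[i], side="right")
    return seq


def _stationary(trans: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(trans.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_epoch_series(profile: ActivityProfile, n_participants: int,
                          seed: int, start_date: str = "2013-01-07",
                          participant_offset: int = 0) -> pd.DataFrame:
    """Simulate 60-s epoch traces for a cohort.

    Returns a tidy frame with one row per waking epoch:
    ``participant_id, day_index, epoch_index, timestamp_iso8601, enmo_mg,
    waking, state`` — ``state`` is the generating ground truth and is not
    part of the on-disk epoch dialect. ``epoch_index`` counts 60-s epochs
    from midnight of each day.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    states = profile.states
    k = len(states)
    if k > 1:
        trans = np.array([[profile.transition[a].get(b, 0.0) for b in states]
                          for a in states])
        start_p = _stationary(trans)
    wake_epoch0 = int(round(profile.waking_start_hour * 60))
    base = pd.Timestamp(start_date)

    frames = []
    for pid in range(n_participants):
        z = rng.standard_normal() * (1.0 if profile.between_sd > 0 else 0.0)
        bout_scale = {s: float(np.exp(_BOUT_RE_COEF[s] * profile.between_sd * z))
                      for s in states}
        emit_scale = {s: float(np.exp(_EMIT_RE_COEF[s] * profile.between_sd * z))
                      for s in states}
        waking = int(np.clip(
            round(rng.normal(profile.waking_minutes, profile.waking_sd_minutes)),
            1, 1440 - wake_epoch0))
        mean_bout = np.mean([profile.bout_dist[s].mean_minutes * bout_scale[s]
                             for s in states])
        n_guess = int(waking / max(mean_bout, 1.0) * 1.6) + 20
        for day in range(profile.days):
            # states then lengths until the waking period is tiled
            if k == 1:
                seq = np.zeros(n_guess, dtype=np.int64)
            else:
                seq = _sample_state_sequence(rng, states, trans, start_p, n_guess)
            lengths = np.empty(n_guess, dtype=np.int64)
            for j, s in enumerate(states):
                idx = np.flatnonzero(seq == j)
                if idx.size:
                    lengths[idx] = profile.bout_dist[s].sample(
                        rng, idx.size, bout_scale[s])
            while lengths.sum() < waking:  # rare top-up
                extra_states = (_sample_state_sequence(rng, states, trans,
                                                       start_p, 40)
                                if k > 1 else np.zeros(40, dtype=np.int64))
                extra = np.empty(40, dtype=np.int64)
                for j, s in enumerate(states):
                    idx = np.flatnonzero(extra_states == j)
                    if idx.size:
                        extra[idx] = profile.bout_dist[s].sample(
                            rng, idx.size, bout_scale[s])
                seq = np.concatenate([seq, extra_states])
                lengths = np.concatenate([lengths, extra])
            cum = np.cumsum(lengths)
            nb = int(np.searchsorted(cum, waking)) + 1
            seq, lengths = seq[:nb], lengths[:nb].copy()
            lengths[-1] -= cum[nb - 1] - waking  # truncate to tile exactly

            epoch_state = np.repeat(seq, lengths)
            enmo = np.empty(waking)
            for j, s in enumerate(states):
                mask = epoch_state == j
                if mask.any():
                    enmo[mask] = profile.emission[s].sample(
                        rng, int(mask.sum()), emit_scale[s])
            frames.append(pd.DataFrame({
                "participant_id": participant_offset + pid,
                "day_index": day,
                "epoch_index": np.arange(wake_epoch0, wake_epoch0 + waking),
                "enmo_mg": enmo,
                "waking": 1,
                "state": np.asarray(states, dtype=object)[epoch_state],
            }))
    out = pd.concat(frames, ignore_index=True)
    out["timestamp_iso8601"] = (
        base
        + pd.to_timedelta(out["day_index"], unit="D")
        + pd.to_timedelta(out["epoch_index"] * 60, unit="s"))
    cols = ["participant_id", "day_index", "epoch_index", "timestamp_iso8601",
            "enmo_mg", "waking", "state"]
    return out[cols]


def write_epoch_csv(epochs: pd.DataFrame, path) -> None:
    """Write the epoch dialect (ground-truth state column dropped)."""
    cols = ["participant_id", "day_index", "epoch_index", "timestamp_iso8601",
            "enmo_mg", "waking"]
    out = epochs[cols].copy()
    out["timestamp_iso8601"] = pd.to_datetime(
        out["timestamp_iso8601"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.4f")


def read_epoch_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp_iso8601"] = pd.to_datetime(df["timestamp_iso8601"])
    return df


@dataclass
class CovariateSpec:
    """One confounder column: 'normal' (mean, sd) or 'bernoulli' (p)."""

    name: str
    dist: str
    params: tuple
    beta: float = 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "normal":
            return rng.normal(self.params[0], self.params[1], size=n)
        if self.dist == "bernoulli":
            return (rng.random(n) < self.params[0]).astype(float)
        raise SimulationError(f"unknown covariate distribution {self.dist!r}")


def default_covariates() -> list[CovariateSpec]:
    """Age-like and sex-like confounders with their own mortality effects."""
    return [
        CovariateSpec("age", "normal", (69.4, 5.5), beta=0.09),
        CovariateSpec("female", "bernoulli", (0.26,), beta=-0.45),
    ]


def one_factor_correlation(names: tuple[str, ...] = FEATURE_NAMES,
                           scale: float = 1.0) -> np.ndarray:
    """PSD correlation matrix from the built-in one-factor loadings."""
    lam = np.array([_FACTOR_LOADINGS[n] * scale for n in names])
    r = np.outer(lam, lam)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class CohortSpec:
    """Participant-level cohort: correlated features + PH mortality process.

    ``beta`` maps feature name -> log hazard ratio per SD of that feature.
    The default baseline rate and 8-year administrative horizon give a
    marginal event fraction near 10%.
    """

    n: int
    feature_names: tuple[str, ...] = FEATURE_NAMES
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    correlation: np.ndarray | None = None
    beta: dict[str, float] = field(default_factory=dict)
    covariates: list[CovariateSpec] = field(default_factory=default_covariates)
    baseline_rate: float = 0.0132
    weibull_shape: float = 1.0
    horizon_years: float = 8.0
    censoring_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.feature_names)
        if self.means is None:
            self.means = np.array(
                [FEATURE_STATS.get(f, (0.0, 1.0))[0] for f in self.feature_names])
        if self.sds is None:
            self.sds = np.array(
                [FEATURE_STATS.get(f, (0.0, 1.0))[1] for f in self.feature_names])
        if self.correlation is None:
            if set(self.feature_names) <= set(_FACTOR_LOADINGS):
                self.correlation = one_factor_correlation(self.feature_names)
            else:
                self.correlation = np.eye(p)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (p, p):
            raise SimulationError("correlation matrix shape mismatch")
        if not np.allclose(self.correlation, self.correlation.T, atol=1e-10):
            raise SimulationError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise SimulationError("correlation diagonal must be 1")
        eigvals = np.linalg.eigvalsh(self.correlation)
        if eigvals[0] < -1e-10:
            raise SimulationError(
                f"correlation matrix not positive semi-definite: smallest "
                f"eigenvalue {eigvals[0]:.3e}")
        unknown = set(self.beta) - set(self.feature_names)
        if unknown:
            raise SimulationError(f"beta refers to unknown features {unknown}")
        if self.horizon_years <= 0:
            raise SimulationError("censoring horizon must be positive")
        if self.baseline_rate <= 0 or self.weibull_shape <= 0:
            raise SimulationError("baseline hazard parameters must be positive")


@dataclass
class GroundTruth:
    """What the generator knows and the analysis is meant to recover."""

    support: tuple[str, ...]
    beta: dict[str, float]
    linear_predictor: np.ndarray
    event_fraction: float

    def to_dict(self) -> dict:
        return {
            "support": list(self.support),
            "beta": dict(self.beta),
            "event_fraction": self.event_fraction,
        }


def _true_event_fraction(spec: CohortSpec, lp: np.ndarray) -> float:
    """P(event observed) under Weibull PH, exp. censoring and the horizon."""
    if lp.size == 0:
        return float("nan")
    h, k, mu = spec.horizon_years, spec.weibull_shape, spec.censoring_rate
    t = np.linspace(1e-9, h, 257)
    rate_i = spec.baseline_rate * np.exp(lp)[:, None]
    haz = rate_i * k * t[None, :] ** (k - 1)
    surv = np.exp(-rate_i * t[None, :] ** k)
    integrand = haz * surv * np.exp(-mu * t[None, :])
    return float(np.mean(simpson(integrand, x=t)))


def simulate_feature_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the feature table (Gaussian copula) and its ground truth.

    Marginals are normal with the requested means/SDs; the dependence
    structure is the requested correlation matrix. The latent linear
    predictor combines per-SD feature effects (on the standardized scale)
    and covariate effects (on the natural scale, centred).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n, p = spec.n, len(spec.feature_names)
    # eigendecomposition square root: stable for semi-definite matrices
    vals, vecs = np.linalg.eigh(spec.correlation)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
    z = rng.standard_normal((n, p)) @ root.T
    X = spec.means + spec.sds * z
    df = pd.DataFrame(X, columns=list(spec.feature_names))

    beta_vec = np.array([spec.beta.get(f, 0.0) for f in spec.feature_names])
    lp = z @ beta_vec  # per-SD effects act on the standardized scale
    for cov in spec.covariates:
        x = cov.sample(rng, n)
        df[cov.name] = x
        if n > 0:
            lp = lp + cov.beta * (x - x.mean())
    support = tuple(f for f in spec.feature_names
                    if spec.beta.get(f, 0.0) != 0.0)
    truth = GroundTruth(support, dict(spec.beta), lp,
                        _true_event_fraction(spec, lp))
    return df, truth


def cohort_spec_from_yaml(path) -> CohortSpec:
    """Build a CohortSpec from a YAML file of scalar fields + a beta map.

    Recognised keys are the scalar CohortSpec fields (n, baseline_rate,
    weibull_shape, horizon_years, censoring_rate, seed) plus ``beta``
    (feature name -> per-SD log HR) and optional ``correlation_scale``
    applied to the built-in one-factor loadings.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scale = raw.pop("correlation_scale", None)
    kwargs = {}
    for key in ("n", "baseline_rate", "weibull_shape", "horizon_years",
                "censoring_rate", "seed", "beta"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise SimulationError(f"unknown cohort spec keys {sorted(raw)}")
    if scale is not None:
        kwargs["correlation"] = one_factor_correlation(scale=float(scale))
    return CohortSpec(**kwargs)


def simulate_survival(linear_predictor: np.ndarray, spec: CohortSpec,
                      seed: int | None = None) -> pd.DataFrame:
    """Event/censoring times under the proportional-hazards process.

    hazard(t) = baseline_rate * shape * t^(shape-1) * exp(lp); observed time
    is the minimum of the event time, an exponential random-censoring time
    (if ``censoring_rate`` > 0) and the administrative horizon.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed + 1 if seed is None else seed))
    lp = np.asarray(linear_predictor, dtype=float)
    n = lp.size
    e = rng.exponential(size=n)
    t_event = (e / (spec.baseline_rate * np.exp(lp))) ** (1.0 / spec.weibull_shape)
    t_cens = np.full(n, spec.horizon_years)
    if spec.censoring_rate > 0:
        t_cens = np.minimum(t_cens, rng.exponential(1.0 / spec.censoring_rate,
                                                    size=n))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # avoid exact-zero follow-up, which survival software rejects
    time = np.maximum(time, 1e-8)
    return pd.DataFrame({"time_years": time, "event": event})
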