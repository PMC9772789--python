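"""The 21 physical-activity / sedentary-behaviour features from 60-s epochs.

Epochs are classified into intensity classes by fixed ENMO thresholds
(SB < 40 mg <= LIPA < 100 mg <= MVPA), bouts are maximal uninterrupted runs
of one class within a day's waking period, and the feature vector covers six
dimensions of movement behaviour: overall activity level, total duration,
bout duration, frequency, intensity distribution and timing.

Per-day quantities are averaged over retained days with equal weight, except
the mean bout durations which are ratios of sums (total class time over
total bout count) so the identity ``mean_bout * n_bouts = duration`` holds
at the participant level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import FEATURE_NAMES, MVPA_THRESHOLD, SB_THRESHOLD

STATE_CODES = {"SB": 0, "LIPA": 1, "MVPA": 2}
_CODE_NAMES = np.array(["SB", "LIPA", "MVPA"], dtype=object)

DURATION_FEATURES = ("dur_SB", "dur_LIPA", "dur_MVPA",
                     "sb_lt10", "sb_10_30", "sb_ge30",
                     "lipa_lt10", "lipa_ge10", "mvpa_lt10", "mvpa_ge10")
COUNT_FEATURES = ("n_bouts_SB", "n_bouts_LIPA", "n_bouts_MVPA")


def classify_epochs(enmo_mg: np.ndarray, waking: np.ndarray | None = None,
                    sb_threshold: float = SB_THRESHOLD,
                    mvpa_threshold: float = MVPA_THRESHOLD) -> np.ndarray:
    """Label waking epochs 0=SB, 1=LIPA, 2=MVPA; non-waking epochs get -1.

    Boundary semantics: SB is [0, sb_threshold), LIPA [sb_threshold,
    mvpa_threshold), MVPA [mvpa_threshold, inf).
    """
    if not (0 < sb_threshold < mvpa_threshold):
        raise ValueError(
            f"thresholds must satisfy 0 < sb < mvpa, got "
            f"({sb_threshold}, {mvpa_threshold})")
    a = np.asarray(enmo_mg, dtype=float)
    neg = np.flatnonzero(a < 0)
    if neg.size:
        raise ValueError(f"negative acceleration at epoch {neg[0]}: {a[neg[0]]}")
    labels = np.where(a >= mvpa_threshold, 2, np.where(a >= sb_threshold, 1, 0))
    if waking is not None:
        labels = np.where(np.asarray(waking).astype(bool), labels, -1)
    return labels.astype(np.int64)


def detect_bouts(labels: np.ndarray) -> pd.DataFrame:
    """Run-length encode one day's labels into maximal same-state bouts.

    Non-waking epochs (label -1) terminate bouts and appear in no bout.
    Returns columns ``state`` (code), ``start`` (epoch offset), ``length``
    (minutes).
    """
    lab = np.asarray(labels)
    if lab.size == 0:
        return pd.DataFrame({"state": [], "start": [], "length": []})
    change = np.flatnonzero(np.diff(lab) != 0) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [lab.size]]))
    states = lab[starts]
    keep = states >= 0
    return pd.DataFrame({"state": states[keep], "start": starts[keep],
                         "length": lengths[keep]})


def _day_tabulate(labels: np.ndarray, enmo: np.ndarray) -> dict:
    """Bout/duration tabulation for one day's waking labels."""
    bouts = detect_bouts(labels)
    out = {}
    for name, code in STATE_CODES.items():
        sub = bouts[bouts["state"] == code]
        out[f"dur_{name}"] = float(sub["length"].sum())
        out[f"n_bouts_{name}"] = float(len(sub))
    sb = bouts[bouts["state"] == 0]["length"].to_numpy()
    out["sb_lt10"] = float(sb[sb < 10].sum())
    out["sb_10_30"] = float(sb[(sb >= 10) & (sb < 30)].sum())
    out["sb_ge30"] = float(sb[sb >= 30].sum())
    lipa = bouts[bouts["state"] == 1]["length"].to_numpy()
    out["lipa_lt10"] = float(lipa[lipa < 10].sum())
    out["lipa_ge10"] = float(lipa[lipa >= 10].sum())
    mvpa = bouts[bouts["state"] == 2]["length"].to_numpy()
    out["mvpa_lt10"] = float(mvpa[mvpa < 10].sum())
    out["mvpa_ge10"] = float(mvpa[mvpa >= 10].sum())
    waking_mask = labels >= 0
    out["waking_minutes"] = float(waking_mask.sum())
    out["accel_sum"] = float(enmo[waking_mask].sum())
    return out


def intensity_distribution(enmo_by_day: list[np.ndarray],
                           bin_width: float = 25.0) -> tuple[float, float]:
    """Intercept and gradient of the log-log intensity/time relationship.

    Waking epochs of all days are pooled into fixed-width intensity bins
    starting at 0 mg; minutes per bin are expressed per day; ordinary least
    squares of ln(minutes/day in bin) on ln(bin midpoint) over non-empty
    bins gives (intercept, gradient). The gradient is invariant to the
    per-day scaling, which only shifts the intercept.
    """
    pooled = np.concatenate([np.asarray(d, dtype=float) for d in enmo_by_day])
    n_days = len(enmo_by_day)
    # extend one bin past the maximum: histogram's last bin is right-closed,
    # so an edge at exactly max would misplace the top epoch one bin down
    edges = np.arange(0.0, pooled.max() + 2 * bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    counts, _ = np.histogram(pooled, bins=edges)
    mid = (edges[:-1] + edges[1:]) / 2.0
    nz = counts > 0
    if nz.sum() < 2:
        raise ValueError("fewer than 2 non-empty intensity bins; "
                         "gradient undefined")
    y = np.log(counts[nz] / n_days)
    x = np.log(mid[nz])
    gradient, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(gradient)


def timing_m5(enmo_by_day: list[np.ndarray], epoch0_by_day: list[int],
              window_epochs: int = 300) -> float:
    """Mean start clock-hour of the most active 5 consecutive waking hours.

    Per day, the window of ``window_epochs`` consecutive waking epochs with
    the maximal summed acceleration is located (earliest window on ties);
    its start is converted to clock hours using the day's first waking
    epoch index, then averaged over days. Days with fewer waking epochs
    than the window are skipped; an error is raised if no day qualifies.
    """
    starts = []
    for enmo, e0 in zip(enmo_by_day, epoch0_by_day):
        a = np.asarray(enmo, dtype=float)
        if a.size < window_epochs:
            continue
        c = np.concatenate([[0.0], np.cumsum(a)])
        sums = c[window_epochs:] - c[:-window_epochs]
        i = int(np.argmax(sums))  # argmax returns the first maximum
        starts.append((e0 + i) / 60.0)
    if not starts:
        raise ValueError("waking period shorter than 5 h on every day")
    return float(np.mean(starts))


def extract_features(epochs: pd.DataFrame, sb_threshold: float = SB_THRESHOLD,
                     mvpa_threshold: float = MVPA_THRESHOLD,
                     bin_width: float = 25.0) -> pd.Series:
    """All 21 features for one participant's epoch frame.

    ``epochs`` uses the epoch dialect (``day_index, epoch_index, enmo_mg,
    waking``); rows with ``waking == 0`` are excluded from every feature.
    """
    days = []
    enmo_by_day, epoch0_by_day = [], []
    mvpa30 = 0
    for _, day in epochs.groupby("day_index", sort=True):
        day = day.sort_values("epoch_index")
        labels = classify_epochs(day["enmo_mg"].to_numpy(),
                                 day["waking"].to_numpy(),
                                 sb_threshold, mvpa_threshold)
        if not (labels >= 0).any():
            continue
        tab = _day_tabulate(labels, day["enmo_mg"].to_numpy())
        days.append(tab)
        if tab["dur_MVPA"] >= 30:
            mvpa30 += 1
        wak = labels >= 0
        enmo_by_day.append(day["enmo_mg"].to_numpy()[wak])
        epoch0_by_day.append(int(day["epoch_index"].to_numpy()[wak][0]))
    if not days:
        raise ValueError("no retained days with waking epochs")
    tabs = pd.DataFrame(days)
    fv = {}
    for col in DURATION_FEATURES + COUNT_FEATURES:
        fv[col] = float(tabs[col].mean())
    fv["mean_acceleration"] = float(tabs["accel_sum"].sum()
                                    / tabs["waking_minutes"].sum())
    for s in STATE_CODES:
        total_n = tabs[f"n_bouts_{s}"].sum()
        fv[f"mean_bout_{s}"] = (float(tabs[f"dur_{s}"].sum() / total_n)
                                if total_n > 0 else 0.0)
    fv["days_mvpa30"] = float(mvpa30)
    fv["intensity_intercept"], fv["intensity_gradient"] = (
        intensity_distribution(enmo_by_day, bin_width))
    fv["timing_pa"] = timing_m5(enmo_by_day, epoch0_by_day)
    fv["waking_minutes"] = float(tabs["waking_minutes"].mean())
    return pd.Series(fv)[list(FEATURE_NAMES) + ["waking_minutes"]]


def extract_cohort(epochs: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Feature table for a multi-participant epoch frame (one row each)."""
    rows = {pid: extract_features(sub, **kwargs)
            for pid, sub in epochs.groupby("participant_id", sort=True)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "participant_id"
    return out


def standardize_by_waking(fv: pd.Series, waking_minutes: float | None = None,
                          reference_minutes: float = 960.0) -> pd.Series:
    """Rescale duration and bout-count features to a reference waking period.

    Durations and counts are multiplied by reference/actual waking minutes;
    mean bout durations (ratios), the day count with >=30 min MVPA,
    overall activity level, intensity and timing features are unchanged,
    so the tiling and mean*count identities survive the rescaling.
    """
    actual = waking_minutes if waking_minutes is not None \
        else fv.get("waking_minutes")
    if actual is None or not np.isfinite(actual) or actual <= 0:
        raise ValueError(f"waking duration must be positive, got {actual}")
    out = fv.copy()
    factor = reference_minutes / float(actual)
    for col in DURATION_FEATURES + COUNT_FEATURES:
        out[col] = fv[col] * factor
    if "waking_minutes" in out.index:
        out["waking_minutes"] = reference_minutes
    return out


def standardize_cohort_by_waking(features: pd.DataFrame,
                                 reference_minutes: float = 960.0
                                 ) -> pd.DataFrame:
    return features.apply(
        lambda row: standardize_by_waking(row,
                                          reference_minutes=reference_minutes),
        axis=1)
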