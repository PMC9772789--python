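"""Prediction-performance metrics for censored survival outcomes."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .cox import CoxPH, _as_time_event

#: Royston-Sauerbrei scaling constant for normal order-statistic scores
KAPPA = np.sqrt(8.0 / np.pi)


def harrell_c(linear_predictor, y) -> float:
    """Harrell's concordance for a risk score (higher score = higher risk).

    A pair (i, j) is comparable when t_i < t_j and participant i had the
    event; it is concordant when lp_i > lp_j, and tied predictors earn half
    credit.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite predictor values")
    t, d = _as_time_event(y)
    ev = np.flatnonzero(d == 1)
    if ev.size == 0:
        raise ValueError("no comparable pairs: no events")
    conc = ties = npairs = 0
    for k in range(0, ev.size, 256):
        sel = ev[k:k + 256]
        comp = t[sel][:, None] < t[None, :]
        diff = lp[sel][:, None] - lp[None, :]
        conc += int((comp & (diff > 0)).sum())
        ties += int((comp & (diff == 0)).sum())
        npairs += int(comp.sum())
    if npairs == 0:
        raise ValueError("no comparable pairs")
    return (conc + 0.5 * ties) / npairs


def royston_r2d(linear_predictor, y, ties: str = "efron") -> float:
    """Royston & Sauerbrei's R^2_D explained-variation measure.

    The predictor is rank-transformed to standard-normal order-statistic
    (Blom) scores scaled by kappa = sqrt(8/pi); the Cox coefficient of that
    regressor is the prognostic-separation statistic D, and
    R^2_D = (D^2/kappa^2) / (pi^2/6 + D^2/kappa^2).
    """
    lp = np.asarray(linear_predictor, dtype=float)
    n = lp.size
    if np.unique(lp).size < 2:
        warnings.warn("constant predictor: R^2_D set to 0", stacklevel=2)
        return 0.0
    ranks = stats.rankdata(lp, method="average")
    rankit = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    z = rankit / KAPPA
    d_stat = CoxPH(ties=ties).fit(z[:, None], y).coef_[0]
    num = d_stat ** 2 / KAPPA ** 2
    return float(num / (np.pi ** 2 / 6.0 + num))


def youden_cutoff(risk_score, y) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J for the observed-event classification.

    The binary label is the event indicator (any observed event during
    follow-up counts as positive; censoring time is ignored — a documented
    simplification). All midpoints between consecutive unique scores are
    scanned; the smallest maximizing cutoff wins ties. Returns
    (cutoff, sensitivity %, specificity %).
    """
    s = np.asarray(risk_score, dtype=float)
    _, d = _as_time_event(y)
    pos, neg = s[d == 1], s[d == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("constant risk score")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    pos_s, neg_s = np.sort(pos), np.sort(neg)
    # positive call: score > cutoff
    sens = 1.0 - np.searchsorted(pos_s, cuts, side="right") / pos.size
    spec = np.searchsorted(neg_s, cuts, side="right") / neg.size
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first (smallest-cutoff) maximum
    return float(cuts[best]), float(sens[best] * 100), float(spec[best] * 100)
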