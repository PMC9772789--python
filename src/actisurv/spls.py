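"""Sparse partial least squares for censored outcomes.

The composite-score derivation works on deviance residuals of a
covariate-free survival model: the Nelson-Aalen cumulative hazard gives
martingale residuals m_i = delta_i - Lambda0(t_i), which are symmetrized to
deviance residuals and used as the working response of a PLS fit whose
weight vectors are soft-thresholded. Soft-thresholding performs variable
selection (features with small covariance with the residual are zeroed) and
the surviving weighted sums are the composite scores, standardized to SD 1
in the derivation cohort so downstream hazard ratios read per SD.

The sparsity parameter eta in [0, 1) is the zeroing threshold as a fraction
of the largest absolute covariance; eta and the number of components are
tuned by event-stratified cross-validation of Harrell's C on held-out folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import StratifiedKFold

from .cox import CoxPH, _as_time_event
from .metrics import harrell_c


class EmptySelectionError(ValueError):
    """Soft-thresholding removed every feature."""


def nelson_aalen(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at each subject's time."""
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    order = np.argsort(t, kind="stable")
    ts, ds = t[order], d[order]
    n = t.size
    uniq, first, counts = np.unique(ts[ds == 1], return_index=True,
                                    return_counts=True)
    at_risk = n - np.searchsorted(ts, uniq, side="left")
    cumhaz = np.cumsum(counts / at_risk)
    idx = np.searchsorted(uniq, t, side="right")
    ch = np.concatenate([[0.0], cumhaz])
    return ch[idx]


def null_deviance_residuals(y) -> tuple[np.ndarray, np.ndarray]:
    """Martingale and deviance residuals of the covariate-free null model.

    m_i = delta_i - Lambda0(t_i);
    d_i = sign(m_i) * sqrt(-2 * [m_i + delta_i * ln(delta_i - m_i)]),
    with the delta_i * ln(.) term zero for censored subjects.
    """
    t, d = _as_time_event(y)
    if d.sum() < 1:
        raise ValueError("at least one event is required")
    lam = nelson_aalen(t, d)
    m = d - lam
    inner = m.copy()
    ev = d == 1
    with np.errstate(divide="ignore"):
        inner[ev] = m[ev] + np.log(np.maximum(d[ev] - m[ev], 1e-300))
    dev = np.sign(m) * np.sqrt(np.maximum(-2.0 * inner, 0.0))
    dev[m == 0] = 0.0
    return m, dev


def soft_threshold(v: np.ndarray, eta: float) -> np.ndarray:
    """Componentwise shrinkage by eta * max|v|; eta = 0 is the identity."""
    if not (0.0 <= eta < 1.0):
        raise ValueError(f"eta must be in [0, 1), got {eta}")
    v = np.asarray(v, dtype=float)
    if not np.any(v != 0):
        raise EmptySelectionError("all-zero covariance vector")
    if eta == 0.0:
        return v.copy()
    lam = eta * np.max(np.abs(v))
    out = np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)
    if not np.any(out != 0):
        raise EmptySelectionError(f"eta={eta} zeroed every component")
    return out


def _spls_core(Xs: np.ndarray, d: np.ndarray, n_components: int, eta: float):
    """NIPALS-style sparse PLS with X- and response-deflation.

    Returns (W weights, P x-loadings, T raw scores, q response loadings).
    """
    n, p = Xs.shape
    Xk = Xs.copy()
    dk = d - d.mean()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for k in range(n_components):
        cov = Xk.T @ dk
        try:
            w = soft_threshold(cov, eta)
        except EmptySelectionError as err:
            raise EmptySelectionError(
                f"empty selection at component {k + 1} (eta={eta})") from err
        w = w / np.linalg.norm(w)
        t = Xk @ w
        denom = float(t @ t)
        if denom <= 0:
            raise EmptySelectionError(
                f"degenerate score at component {k + 1} (eta={eta})")
        p_load = Xk.T @ t / denom
        q[k] = float(dk @ t / denom)
        W[:, k], P[:, k], T[:, k] = w, p_load, t
        Xk = Xk - np.outer(t, p_load)
        dk = dk - q[k] * t
    return W, P, T, q


class SparsePLSCoxScorer(BaseEstimator, TransformerMixin):
    """Derive sparse composite activity scores predictive of mortality.

    Parameters
    ----------
    n_components : number of composite scores K (component 1 is
        "composite score 1", component 2 "composite score 2").
    eta : sparsity fraction in [0, 1); 0 disables selection (plain PLS).
    ties : tie method for the internal Cox fits used in tuning.

    Fitted attributes
    -----------------
    ``x_mean_``, ``x_std_`` : standardization constants (SD with ddof=1);
    ``weights_`` (p, K) unit-norm sparse weight vectors;
    ``loadings_`` (p, K) regression loadings of X on each score;
    ``corr_loadings_`` (p, K) correlations of features with each score;
    ``selected_`` : tuple of selected feature names per component;
    ``scores_`` (n, K) standardized derivation-cohort scores;
    ``score_mean_``, ``score_std_`` : score standardization constants;
    ``cv_trace_`` : tuning grid results when fit via :func:`tune`.
    """

    def __init__(self, n_components: int = 2, eta: float = 0.0,
                 ties: str = "efron"):
        self.n_components = n_components
        self.eta = eta
        self.ties = ties

    def fit(self, X, y):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        Xv, names = self._validate(X)
        n, p = Xv.shape
        self.feature_names_in_ = names
        self.x_mean_ = Xv.mean(axis=0)
        self.x_std_ = Xv.std(axis=0, ddof=1)
        if np.any(self.x_std_ <= 0):
            bad = names[int(np.argmax(self.x_std_ <= 0))]
            raise ValueError(f"zero-variance feature {bad!r}")
        Xs = (Xv - self.x_mean_) / self.x_std_
        _, dev = null_deviance_residuals(y)
        self.deviance_residuals_ = dev
        W, P, T, q = _spls_core(Xs, dev, self.n_components, self.eta)
        self.weights_ = W
        self.loadings_ = P
        self.q_ = q
        # rotation turning standardized features into raw scores directly
        self.rotation_ = W @ np.linalg.inv(P.T @ W)
        self.score_mean_ = T.mean(axis=0)
        self.score_std_ = T.std(axis=0, ddof=1)
        if np.any(self.score_std_ <= 0):
            raise EmptySelectionError("zero-variance component score")
        self.scores_ = (T - self.score_mean_) / self.score_std_
        Ts = self.scores_
        self.corr_loadings_ = np.column_stack([
            [np.corrcoef(Xs[:, j], Ts[:, k])[0, 1] for j in range(p)]
            for k in range(self.n_components)]).reshape(p, self.n_components)
        self.selected_ = tuple(
            tuple(np.asarray(names)[W[:, k] != 0])
            for k in range(self.n_components))
        return self

    def _validate(self, X):
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                missing = [c for c in self.feature_names_in_
                           if c not in X.columns]
                if missing:
                    raise KeyError(f"missing feature column {missing[0]!r}")
                return X[self.feature_names_in_].to_numpy(dtype=float), \
                    list(self.feature_names_in_)
            return X.to_numpy(dtype=float), list(X.columns)
        X = np.asarray(X, dtype=float)
        if hasattr(self, "feature_names_in_"):
            if X.shape[1] != len(self.feature_names_in_):
                raise KeyError(
                    f"expected {len(self.feature_names_in_)} feature columns")
            return X, list(self.feature_names_in_)
        return X, [f"x{j}" for j in range(X.shape[1])]

    def transform(self, X, standardization: str = "derivation") -> np.ndarray:
        """Standardized composite scores for new participants.

        ``derivation`` reuses the stored feature and score constants;
        ``local`` recomputes both on the new table (output SD exactly 1),
        which makes the scores invariant to affine rescaling of the
        features — appropriate when device placement differs between
        cohorts.
        """
        if standardization not in ("derivation", "local"):
            raise ValueError(f"unknown standardization {standardization!r}")
        Xv, _ = self._validate(X)
        if standardization == "derivation":
            Xs = (Xv - self.x_mean_) / self.x_std_
            T = Xs @ self.rotation_
            return (T - self.score_mean_) / self.score_std_
        mu = Xv.mean(axis=0)
        sd = Xv.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            j = int(np.argmax(sd <= 0))
            raise ValueError(
                f"zero-variance feature {self.feature_names_in_[j]!r} under "
                f"local standardization")
        T = ((Xv - mu) / sd) @ self.rotation_
        tm, tsd = T.mean(axis=0), T.std(axis=0, ddof=1)
        if np.any(tsd <= 0):
            raise ValueError("zero-variance score under local standardization")
        return (T - tm) / tsd

    def to_json(self) -> str:
        payload = {
            "feature_names": list(self.feature_names_in_),
            "n_components": int(self.n_components),
            "eta": float(self.eta),
            "x_mean": self.x_mean_.tolist(),
            "x_std": self.x_std_.tolist(),
            "weights": self.weights_.tolist(),
            "loadings": self.loadings_.tolist(),
            "corr_loadings": self.corr_loadings_.tolist(),
            "rotation": self.rotation_.tolist(),
            "score_mean": self.score_mean_.tolist(),
            "score_std": self.score_std_.tolist(),
            "selected": [list(s) for s in self.selected_],
            "cv_trace": (self.cv_trace_.to_dict(orient="list")
                         if hasattr(self, "cv_trace_") else None),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SparsePLSCoxScorer":
        d = json.loads(text)
        obj = cls(n_components=d["n_components"], eta=d["eta"])
        obj.feature_names_in_ = d["feature_names"]
        for attr, key in [("x_mean_", "x_mean"), ("x_std_", "x_std"),
                          ("weights_", "weights"), ("loadings_", "loadings"),
                          ("corr_loadings_", "corr_loadings"),
                          ("rotation_", "rotation"),
                          ("score_mean_", "score_mean"),
                          ("score_std_", "score_std")]:
            setattr(obj, attr, np.asarray(d[key], dtype=float))
        obj.selected_ = tuple(tuple(s) for s in d["selected"])
        if d.get("cv_trace") is not None:
            obj.cv_trace_ = pd.DataFrame(d["cv_trace"])
        return obj


def fit_spls_components(X, y, n_components: int, eta: float,
                        ties: str = "efron") -> SparsePLSCoxScorer:
    """Convenience wrapper: fit the scorer at fixed (K, eta)."""
    return SparsePLSCoxScorer(n_components=n_components, eta=eta,
                              ties=ties).fit(X, y)


def apply_score(model: SparsePLSCoxScorer, new_features,
                standardization: str = "derivation") -> pd.DataFrame:
    """Composite scores for a new cohort, one column per component."""
    T = model.transform(new_features, standardization=standardization)
    idx = (new_features.index if isinstance(new_features, pd.DataFrame)
           else None)
    return pd.DataFrame(
        T, index=idx,
        columns=[f"score_{k + 1}" for k in range(T.shape[1])])


def tune_by_cross_validation(X, y, k_grid=(1, 2),
                             eta_grid=tuple(np.round(np.arange(0, 1.0, 0.1), 1)),
                             folds: int = 5, seed: int = 0,
                             ties: str = "efron"):
    """Grid search (K, eta) by cross-validated Harrell C.

    Folds are stratified on the event indicator. For each cell the scorer is
    fit on the training folds, a Cox model on the training-fold scores gives
    component weights, and the held-out linear predictor is scored by
    Harrell's C; the cell maximizing the fold-mean C wins (first cell in
    grid order on ties, so the result is deterministic under the seed).

    Returns ``(k_star, eta_star, trace)`` with the full grid trace.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(k_grid) == 0 or len(eta_grid) == 0:
        raise ValueError("empty tuning grid")
    t, d = _as_time_event(y)
    if d.sum() < folds:
        raise ValueError(
            f"cannot stratify {int(d.sum())} events into {folds} folds")
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    ydf = pd.DataFrame({"time_years": t, "event": d})
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xdf, d))
    rows = []
    for K in k_grid:
        for eta in eta_grid:
            cs = []
            ok = True
            for tr, va in splits:
                try:
                    scorer = SparsePLSCoxScorer(
                        n_components=K, eta=float(eta), ties=ties)
                    scorer.fit(Xdf.iloc[tr], ydf.iloc[tr])
                    gamma = CoxPH(ties=ties).fit(
                        scorer.scores_, ydf.iloc[tr]).coef_
                    lp_va = scorer.transform(Xdf.iloc[va]) @ gamma
                    cs.append(harrell_c(lp_va, ydf.iloc[va]))
                except (EmptySelectionError, ValueError, RuntimeError):
                    ok = False
                    break
            rows.append({"K": K, "eta": float(eta),
                         "cv_c": float(np.mean(cs)) if ok else np.nan})
    trace = pd.DataFrame(rows)
    if trace["cv_c"].isna().all():
        raise ValueError("every grid cell failed")
    best = int(trace["cv_c"].idxmax())
    return int(trace.loc[best, "K"]), float(trace.loc[best, "eta"]), trace


def derive_scores(X, y, k_grid=(1, 2),
                  eta_grid=tuple(np.round(np.arange(0, 1.0, 0.1), 1)),
                  folds: int = 5, seed: int = 0,
                  ties: str = "efron") -> SparsePLSCoxScorer:
    """Tune (K, eta) by cross-validation, then fit on the full cohort."""
    k_star, eta_star, trace = tune_by_cross_validation(
        X, y, k_grid=k_grid, eta_grid=eta_grid, folds=folds, seed=seed,
        ties=ties)
    scorer = SparsePLSCoxScorer(n_components=k_star, eta=eta_star,
                                ties=ties).fit(X, y)
    scorer.cv_trace_ = trace
    return scorer
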