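"""Super Learner: cross-validated convex stacking of candidate learners.

The ensemble weight vector solves

    min_{w in simplex}  (1/n) sum_i -[ y_i log(Zw)_i + (1-y_i) log(1-(Zw)_i) ]

where Z holds each candidate's held-out (V-fold cross-validated)
probability predictions — the non-negative log-likelihood loss.  The
optimum is found by constrained numerical optimization over the simplex
and each candidate is then refit on the full data for prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold

from .learners import FittedLearner, LearnerSpec

__all__ = ["SLFit", "VIMTable", "fit_super_learner", "predict_sl", "compute_vims",
           "log_loss_clipped"]

EPS = 1e-6


def log_loss_clipped(y: np.ndarray, p: np.ndarray, eps: float = EPS) -> float:
    """Mean negative log-likelihood with predictions clipped to [eps, 1-eps]."""
    p = np.clip(p, eps, 1.0 - eps)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _solve_simplex_weights(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimize CV log-loss of Z @ w over the probability simplex."""
    n, L = Z.shape
    if L == 1:
        return np.ones(1)
    Zc = np.clip(Z, EPS, 1.0 - EPS)
    y = np.asarray(y, dtype=float)

    def objective(w: np.ndarray) -> float:
        p = np.clip(Zc @ w, EPS, 1.0 - EPS)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))

    def grad(w: np.ndarray) -> np.ndarray:
        p = np.clip(Zc @ w, EPS, 1.0 - EPS)
        dldp = -(y / p) + (1.0 - y) / (1.0 - p)
        return Zc.T @ dldp / n

    x0 = np.full(L, 1.0 / L)
    res = minimize(
        objective,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * L,
        constraints=[{"type": "eq", "fun": lambda w: np.sum(w) - 1.0,
                      "jac": lambda w: np.ones(L)}],
        options={"maxiter": 300, "ftol": 1e-10},
    )
    w = np.clip(res.x, 0.0, None)
    s = w.sum()
    if not res.success or s <= 0:
        # fall back to the single best candidate
        risks = [log_loss_clipped(y, Zc[:, j]) for j in range(L)]
        w = np.zeros(L)
        w[int(np.argmin(risks))] = 1.0
        return w
    return w / s


@dataclass
class SLFit:
    """A fitted Super Learner ensemble."""

    learners: list[FittedLearner]
    weights: np.ndarray
    cv_risk: np.ndarray  # per-learner mean held-out negative log-likelihood
    ensemble_cv_risk: float
    fold_assignment: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    @property
    def learner_names(self) -> list[str]:
        return [fl.spec.name for fl in self.learners]


@dataclass
class VIMTable:
    """Per-learner variable importances and dense ranks (1 = most important)."""

    importances: pd.DataFrame  # features x learners
    ranks: pd.DataFrame        # features x learners, permutation of 1..p
    weights: pd.Series         # learner -> ensemble weight


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def fit_super_learner(
    X,
    y,
    library: list[LearnerSpec],
    folds: int = 10,
    seed: int = 0,
) -> SLFit:
    """Fit the stacking ensemble with V-fold cross-validated weights.

    A candidate that raises during any fold is dropped (with a warning)
    and the weights are estimated over the surviving library.
    Deterministic for fixed ``seed``.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome is degenerate: only one class present")
    if len(y) < 10 * folds:
        folds = max(2, len(y) // 10)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(y), dtype=int)
    splits = list(skf.split(Xm, y))
    for k, (_, test_idx) in enumerate(splits):
        fold_of[test_idx] = k

    Z = np.full((len(y), len(library)), np.nan)
    alive = np.ones(len(library), dtype=bool)
    for j, spec in enumerate(library):
        for k, (tr, te) in enumerate(splits):
            try:
                fl = FittedLearner(spec, seed=seed + 1000 * k + j).fit(Xm[tr], y[tr])
                Z[te, j] = fl.predict_proba(Xm[te])
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"learner {spec.name} failed in fold {k}: {exc}")
                alive[j] = False
                break
    dropped = [library[j].name for j in range(len(library)) if not alive[j]]
    if not alive.any():
        raise RuntimeError("every candidate learner failed")
    Z = Z[:, alive]
    kept = [spec for spec, a in zip(library, alive) if a]

    weights = _solve_simplex_weights(Z, y)
    cv_risk = np.array([log_loss_clipped(y, Z[:, j]) for j in range(Z.shape[1])])
    ens_risk = log_loss_clipped(y, np.clip(Z, EPS, 1 - EPS) @ weights)

    fitted = [
        FittedLearner(spec, seed=seed + 7919 * j).fit(Xm, y)
        for j, spec in enumerate(kept)
    ]
    return SLFit(fitted, weights, cv_risk, ens_risk, fold_of, names, dropped)


def predict_sl(fit: SLFit, Xnew) -> np.ndarray:
    """Ensemble probability predictions: the weighted sum of candidates."""
    if isinstance(Xnew, pd.DataFrame) and fit.feature_names:
        missing = [c for c in fit.feature_names if c not in Xnew.columns]
        extra = [c for c in Xnew.columns if c not in fit.feature_names]
        if missing or extra:
            raise ValueError(
                f"column mismatch: missing {missing or 'none'}, extra {extra or 'none'}"
            )
        Xnew = Xnew[fit.feature_names]
    Xm, _ = _as_matrix(Xnew)
    preds = np.column_stack([fl.predict_proba(Xm) for fl in fit.learners])
    return np.clip(preds @ fit.weights, 0.0, 1.0)


def compute_vims(fit: SLFit) -> VIMTable:
    """Variable-importance ranks per learner, 1 = most important.

    Ranks are a permutation of 1..p within each learner; ties are broken
    by (stable) column order so reruns are identical.
    """
    imp = {}
    ranks = {}
    for fl in fit.learners:
        try:
            v = fl.importance()
        except Exception:  # learner without a defined VIM
            warnings.warn(f"learner {fl.spec.name} has no variable importance")
            continue
        order = np.argsort(-v, kind="stable")
        r = np.empty(len(v), dtype=int)
        r[order] = np.arange(1, len(v) + 1)
        imp[fl.spec.name] = v
        ranks[fl.spec.name] = r
    if not imp:
        raise RuntimeError("no learner produced a variable importance")
    index = pd.Index(fit.feature_names, name="variable")
    weights = pd.Series(
        {fl.spec.name: w for fl, w in zip(fit.learners, fit.weights)}
    ).loc[list(imp)]
    return VIMTable(
        pd.DataFrame(imp, index=index),
        pd.DataFrame(ranks, index=index),
        weights,
    )
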