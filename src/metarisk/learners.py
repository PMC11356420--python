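"""Candidate learners for the stacking ensemble.

Three kinds are supported, mirroring the usual binary-risk toolbox:
penalized (elastic net) logistic regression, gradient-boosted trees and
random forests.  Each wrapper exposes the same contract: ``fit``,
``predict_proba`` (probability of class 1) and ``importance`` (the
learner's native variable-importance measure: absolute standardized
coefficient for the elastic net, impurity decrease for the tree
ensembles).

A learner may carry a *screen*: a feature-selection rule applied inside
each training fold before fitting, making the screened learner a
distinct library member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

__all__ = [
    "LearnerSpec",
    "FittedLearner",
    "default_library",
    "fast_library",
    "with_screens",
]

KINDS = ("elastic_net", "boosted_trees", "random_forest")


def screen_top_k_univariate(X: np.ndarray, y: np.ndarray, k: int = 20) -> np.ndarray:
    """Indices of the k features most correlated (point-biserial) with y."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sd = Xc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(Xc.T @ yc) / (sd * yc.std() * len(y) + 1e-12)
    r[sd == 0] = 0.0
    k = min(k, X.shape[1])
    return np.sort(np.argsort(-r, kind="stable")[:k])


def screen_lasso_support(X: np.ndarray, y: np.ndarray, k: int = 20) -> np.ndarray:
    """Support of a moderately penalized L1 logistic fit (fallback: top-k)."""
    scaler = StandardScaler().fit(X)
    clf = LogisticRegression(penalty="l1", solver="liblinear", C=0.5, max_iter=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(scaler.transform(X), y)
    support = np.where(np.abs(clf.coef_[0]) > 1e-10)[0]
    if support.size == 0:
        return screen_top_k_univariate(X, y, k)
    return support


_SCREENS = {
    "top_k_univariate": screen_top_k_univariate,
    "lasso_support": screen_lasso_support,
}


@dataclass(frozen=True)
class LearnerSpec:
    """One member of the candidate library."""

    name: str
    kind: str
    params: dict = field(default_factory=dict)
    screen: str | None = None
    screen_k: int = 20

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if self.screen is not None and self.screen not in _SCREENS:
            raise ValueError(f"unknown screen {self.screen!r}")


class FittedLearner:
    """A fitted library member; remembers its screen's column subset."""

    def __init__(self, spec: LearnerSpec, seed: int):
        self.spec = spec
        self.seed = seed
        self._cols: np.ndarray | None = None
        self._scaler: StandardScaler | None = None
        self._model = None
        self.n_features_: int = 0

    def _make_model(self):
        p = dict(self.spec.params)
        if self.spec.kind == "elastic_net":
            return LogisticRegression(
                penalty="elasticnet",
                solver="saga",
                l1_ratio=p.get("l1_ratio", 0.5),
                C=p.get("C", 1.0),
                max_iter=p.get("max_iter", 2000),
                tol=p.get("tol", 1e-3),
                random_state=self.seed,
            )
        if self.spec.kind == "boosted_trees":
            return GradientBoostingClassifier(
                n_estimators=p.get("n_estimators", 500),
                max_depth=p.get("max_depth", 2),
                learning_rate=p.get("learning_rate", 0.1),
                subsample=p.get("subsample", 1.0),
                n_iter_no_change=p.get("n_iter_no_change", 10),
                validation_fraction=p.get("validation_fraction", 0.15),
                random_state=self.seed,
            )
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 1000),
            max_features=p.get("max_features", "sqrt"),
            min_samples_leaf=p.get("min_samples_leaf", 2),
            n_jobs=1,
            random_state=self.seed,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FittedLearner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.n_features_ = X.shape[1]
        if self.spec.screen is not None:
            self._cols = _SCREENS[self.spec.screen](X, y, self.spec.screen_k)
            X = X[:, self._cols]
        if self.spec.kind == "elastic_net":
            self._scaler = StandardScaler().fit(X)
            X = self._scaler.transform(X)
        self._model = self._make_model()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._model.fit(X, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._cols is not None:
            X = X[:, self._cols]
        if self._scaler is not None:
            X = self._scaler.transform(X)
        return self._model.predict_proba(X)[:, 1]

    def importance(self) -> np.ndarray:
        """Native variable importance, expanded back to the full column set.

        Elastic net: |coefficient| on standardized inputs; tree ensembles:
        total impurity decrease.  Screened-out columns get importance 0.
        """
        if self.spec.kind == "elastic_net":
            imp = np.abs(self._model.coef_[0])
        else:
            imp = np.asarray(self._model.feature_importances_, dtype=float)
        if self._cols is not None:
            full = np.zeros(self.n_features_)
            full[self._cols] = imp
            return full
        return imp

    def coefficient_signs(self) -> np.ndarray | None:
        if self.spec.kind != "elastic_net":
            return None
        signs = np.sign(self._model.coef_[0])
        if self._cols is not None:
            full = np.zeros(self.n_features_)
            full[self._cols] = signs
            return full
        return signs


def default_library() -> list[LearnerSpec]:
    """Full-size library: elastic-net grid, boosted trees, random forest."""
    lib = [
        LearnerSpec(f"enet_a{int(100 * a)}", "elastic_net", {"l1_ratio": a})
        for a in (0.25, 0.5, 0.75, 1.0)
    ]
    lib += [
        LearnerSpec(f"gbm_d{d}", "boosted_trees", {"n_estimators": 500, "max_depth": d})
        for d in (2, 4)
    ]
    lib.append(LearnerSpec("rf_1000", "random_forest", {"n_estimators": 1000}))
    return lib


def fast_library() -> list[LearnerSpec]:
    """Reduced library (one member per kind, small ensembles) for quick runs."""
    return [
        LearnerSpec("enet_a50", "elastic_net", {"l1_ratio": 0.5}),
        LearnerSpec(
            "gbm_d2",
            "boosted_trees",
            {"n_estimators": 60, "max_depth": 2, "n_iter_no_change": 5},
        ),
        LearnerSpec("rf_60", "random_forest", {"n_estimators": 60}),
    ]


def with_screens(library: Sequence[LearnerSpec], k: int = 20) -> list[LearnerSpec]:
    """Augment a library with screened variants of every member."""
    out = list(library)
    for spec in library:
        for screen in ("top_k_univariate", "lasso_support"):
            out.append(
                LearnerSpec(
                    f"{spec.name}_{screen}", spec.kind, dict(spec.params), screen, k
                )
            )
    return out
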