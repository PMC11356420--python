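"""Variable selection: penalized regression, ensemble weighted rank, stability.

Two selectors are implemented.  The lasso selector fits an L1-penalized
logistic path with the base (design) covariates effectively unpenalized
and keeps every variable with a nonzero coefficient at the
cross-validation-chosen penalty.  The ensemble-rank selector combines
each candidate learner's variable-importance ranks using the Super
Learner's convex weights and keeps the top-k variables by weighted rank.

Stability across multiply-imputed datasets: a variable enters the final
set when it is selected in *more than* 70% of the imputed copies (strict
inequality).  Final sets are then unioned across the two selectors and
across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .super_learner import VIMTable, log_loss_clipped

__all__ = [
    "SelectionResult",
    "StabilityTable",
    "lasso_select",
    "sl_rank_select",
    "stability_select",
    "union_final",
]

#: rescaling factor making the L1 penalty on forced columns negligible
_FORCED_SCALE = 1e3


@dataclass
class SelectionResult:
    procedure: str  # "lasso" | "sl_rank"
    selected: list[str]
    diagnostics: pd.Series = field(repr=False, default=None)
    universe: list[str] = field(repr=False, default_factory=list)
    forced: list[str] = field(default_factory=list)
    imputation_index: int | None = None
    platform: str | None = None
    covariate_mode: str | None = None

    def __post_init__(self) -> None:
        if self.universe:
            unknown = set(self.selected) - set(self.universe)
            if unknown:
                raise ValueError(f"selected variables outside universe: {unknown}")


@dataclass
class StabilityTable:
    """Selection frequency across imputations and the final (>threshold) flag."""

    frequency: pd.Series
    final: pd.Series
    threshold: float
    procedure: str

    @property
    def final_set(self) -> list[str]:
        return list(self.final.index[self.final])


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, n_lambdas: int) -> np.ndarray:
    n = len(y)
    resid = y - y.mean()
    lam_max = np.max(np.abs(Xs.T @ resid)) / n
    lam_max = max(lam_max, 1e-4)
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)


def lasso_select(
    X: pd.DataFrame,
    y,
    forced_ids: Sequence[str] = (),
    seed: int = 0,
    n_folds: int = 10,
    n_lambdas: int = 30,
    lambda_rule: str = "min",
) -> SelectionResult:
    """L1 logistic path with forced, effectively-unpenalized base covariates.

    The penalty is tuned by ``n_folds``-fold cross-validated deviance over
    a geometric grid; ``lambda_rule`` picks the minimizing penalty
    (``"min"``) or the largest penalty within one SE (``"1se"``).  The
    output is the forced set plus every variable with a nonzero
    coefficient at the chosen penalty.

    Forced columns are standardized and then rescaled by a large factor
    so their effective L1 penalty is negligible — the per-feature
    penalty-factor-zero construction.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    forced_ids = [str(f) for f in forced_ids]
    missing = set(forced_ids) - set(X.columns)
    if missing:
        raise ValueError(f"forced columns not in X: {sorted(missing)}")
    y = np.asarray(y).astype(int)
    n = len(y)

    cols = list(X.columns)
    forced_mask = np.array([c in forced_ids for c in cols])
    Xs = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    Xs[:, ~np.isfinite(Xs).all(axis=0)] = 0.0  # constant columns
    Xs[:, forced_mask] *= _FORCED_SCALE

    lambdas = _lambda_grid(Xs[:, ~forced_mask] if (~forced_mask).any() else Xs,
                           y, n_lambdas)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xs, y))
    cv_dev = np.zeros((len(lambdas), n_folds))
    for k, (tr, te) in enumerate(splits):
        for i, lam in enumerate(lambdas):
            clf = _l1_fit(Xs[tr], y[tr], lam, seed)
            p = clf.predict_proba(Xs[te])[:, 1]
            cv_dev[i, k] = log_loss_clipped(y[te], p)
    mean_dev = cv_dev.mean(axis=1)
    if lambda_rule == "1se":
        se = cv_dev.std(axis=1, ddof=1) / np.sqrt(n_folds)
        best = int(np.argmin(mean_dev))
        ok = np.where(mean_dev <= mean_dev[best] + se[best])[0]
        choice = int(ok.min())  # grid is ordered large -> small penalty
    else:
        choice = int(np.argmin(mean_dev))

    clf = _l1_fit(Xs, y, lambdas[choice], seed)
    coef = clf.coef_[0].copy()
    coef[forced_mask] *= _FORCED_SCALE  # back to standardized-input scale
    nonzero = [c for c, b, f in zip(cols, np.abs(clf.coef_[0]) > 1e-8, forced_mask)
               if b and not f]
    selected = forced_ids + nonzero
    diag = pd.Series(coef, index=cols, name="lasso_coef_std")
    return SelectionResult("lasso", selected, diag, cols, forced_ids)


def _l1_fit(Xs: np.ndarray, y: np.ndarray, lam: float, seed: int) -> LogisticRegression:
    # sklearn's liblinear minimizes C * loss_sum + ||w||_1;  C = 1/(n*lambda).
    # liblinear also penalizes the intercept; a large intercept_scaling makes
    # that penalty negligible, matching the usual unpenalized-intercept fit.
    C = 1.0 / (len(y) * lam)
    clf = LogisticRegression(
        penalty="l1", solver="liblinear", C=C, max_iter=500, random_state=seed,
        intercept_scaling=100.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y)
    return clf


def sl_rank_select(
    vims: VIMTable,
    weights: pd.Series | None = None,
    k: int = 20,
    forced_ids: Sequence[str] = (),
) -> SelectionResult:
    """Top-k variables by ensemble-weighted importance rank.

    The weighted rank of variable j is sum_l w_l * rank_l(j) with the
    Super Learner's convex weights (renormalized over learners that
    report an importance).  Forced variables do not compete for the k
    slots; they are appended when absent.  Ties are broken by stable
    column order.
    """
    w = vims.weights if weights is None else weights
    w = w.reindex(vims.ranks.columns).fillna(0.0)
    if (w < -1e-12).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    w = w / total if total > 0 else pd.Series(
        1.0 / len(w), index=w.index
    )
    weighted = vims.ranks.to_numpy(dtype=float) @ w.to_numpy()
    weighted = pd.Series(weighted, index=vims.ranks.index, name="weighted_rank")

    forced_ids = [str(f) for f in forced_ids]
    competing = [v for v in weighted.index if v not in forced_ids]
    k_eff = min(k, len(competing))
    order = np.argsort(weighted.loc[competing].to_numpy(), kind="stable")
    top = [competing[i] for i in order[:k_eff]]
    selected = top + [f for f in forced_ids if f not in top]
    return SelectionResult("sl_rank", selected, weighted, list(weighted.index),
                           forced_ids)


def stability_select(
    results: Iterable[SelectionResult], threshold: float = 0.70
) -> StabilityTable:
    """Selection frequency over imputed datasets; final iff freq > threshold."""
    results = list(results)
    if not results:
        raise ValueError("no selection results")
    universe = results[0].universe
    procedure = results[0].procedure
    for r in results[1:]:
        if r.universe != universe:
            raise ValueError("selection results have differing variable universes")
    counts = pd.Series(0.0, index=pd.Index(universe, name="variable"))
    for r in results:
        counts.loc[r.selected] += 1.0
    freq = counts / len(results)
    final = freq > threshold  # strict: 0.70 exactly is not final
    return StabilityTable(freq, final, threshold, procedure)


def union_final(
    sets_by_platform_procedure: Mapping[tuple[str, str], Iterable[str]],
    covariate_names: Iterable[str] = (),
) -> dict:
    """Union stable sets across procedures, then across platforms.

    Returns per-platform unions (over the two selectors), the overall
    metabolite union and the unique covariates selected in any
    platform-level analysis.
    """
    covs = set(covariate_names)
    per_platform: dict[str, set[str]] = {}
    for (platform, _proc), vars_ in sets_by_platform_procedure.items():
        per_platform.setdefault(platform, set()).update(vars_)
    metabolites = sorted(
        set().union(*per_platform.values()) - covs if per_platform else set()
    )
    covariates = sorted(
        (set().union(*per_platform.values()) & covs) if per_platform else set()
    )
    return {
        "per_platform": {p: sorted(s - covs) for p, s in per_platform.items()},
        "metabolites": metabolites,
        "covariates": covariates,
    }
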