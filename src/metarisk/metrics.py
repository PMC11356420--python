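"""Performance metrics: rank-based AUC and proportion of explained variation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = ["auc", "PEVReport", "compute_pev"]


def auc(scores, labels) -> float:
    """Area under the ROC curve, rank-based, ties counted 1/2.

    Equivalent to the Mann-Whitney U statistic divided by n1*n0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    r = rankdata(scores)  # average ranks handle ties as 1/2
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class PEVReport:
    """Proportion of explained variation: corr(outcome, CV predictions)."""

    per_variable: pd.Series
    joint: float
    direction: pd.Series  # "+" / "-" from the full multiple logistic fit


def _cv_logistic_predictions(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int
) -> np.ndarray:
    """Out-of-fold predicted probabilities from a (nearly unpenalized) logistic fit."""
    out = np.empty(len(y))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        out[te] = _safe_logistic(X[tr], y[tr]).predict_proba(X[te])[:, 1]
    return out


def _safe_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Maximum-likelihood logistic fit; ridge fallback under separation."""
    for C in (1e6, 1.0):
        clf = LogisticRegression(C=C, max_iter=1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        if np.all(np.isfinite(clf.coef_)) and np.abs(clf.coef_).max() < 1e4:
            return clf
    return clf


def compute_pev(
    final_variables,
    data: pd.DataFrame,
    base_covariates,
    outcome_col: str = "y",
    folds: int = 5,
    seed: int = 0,
) -> PEVReport:
    """PEV of each selected variable and of the joint selected set.

    Per variable: logistic regression on {base covariates + that
    variable}, out-of-fold predictions correlated with the binary
    outcome.  Joint: same with all selected variables.  Directions come
    from the signs of the full multiple logistic regression coefficients.
    """
    final_variables = [str(v) for v in final_variables]
    if not final_variables:
        raise ValueError("final variable set is empty")
    base = [str(b) for b in base_covariates]
    y = data[outcome_col].to_numpy(dtype=int)
    scaler = StandardScaler()

    def block(cols: list[str]) -> np.ndarray:
        return scaler.fit_transform(data[cols].to_numpy(dtype=float))

    per_var = {}
    for v in final_variables:
        cols = base + ([v] if v not in base else [])
        p = _cv_logistic_predictions(block(cols), y, folds, seed)
        per_var[v] = float(np.corrcoef(y, p)[0, 1])

    all_cols = base + [v for v in final_variables if v not in base]
    p_joint = _cv_logistic_predictions(block(all_cols), y, folds, seed)
    joint = float(np.corrcoef(y, p_joint)[0, 1])

    full = _safe_logistic(block(all_cols), y)
    coefs = pd.Series(full.coef_[0], index=all_cols)
    direction = coefs.loc[[v for v in final_variables if v not in base]].map(
        lambda c: "+" if c > 0 else "-"
    )
    return PEVReport(pd.Series(per_var), joint, direction)
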