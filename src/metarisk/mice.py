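"""Multiple imputation by chained equations, fit without the outcome.

Continuous variables use predictive-mean matching (PMM) on a linear
regression of the other covariates; binary variables use logistic
regression draws.  The case/control label never enters any conditional
model matrix, which keeps the downstream honest cross-validation of
prediction performance valid: imputations cannot leak outcome
information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

__all__ = ["ImputationSet", "impute_covariates_mice"]

log = logging.getLogger(__name__)

_PMM_DONORS = 5
_DEFAULT_SWEEPS = 10


@dataclass
class ImputationSet:
    """m completed copies of one analysis dataset plus provenance.

    ``datasets`` all share index and columns; ``mask`` flags which entries
    were imputed.  Observed entries are identical across copies.
    """

    datasets: list[pd.DataFrame]
    mask: pd.DataFrame

    @property
    def m(self) -> int:
        return len(self.datasets)


def _is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def _design(df: pd.DataFrame, exclude: str) -> np.ndarray:
    X = df.drop(columns=[exclude])
    return X.to_numpy(dtype=float)


def _impute_once(
    num: pd.DataFrame,
    miss: pd.DataFrame,
    binary: dict[str, bool],
    sweeps: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One chained-equations chain: initialize, then Gibbs-style sweeps."""
    work = num.copy()
    # starting values: random draws from the observed marginal
    for var in miss.columns[miss.any()]:
        obs = num[var].dropna().to_numpy()
        idx = miss.index[miss[var]]
        work.loc[idx, var] = rng.choice(obs, size=len(idx), replace=True)

    order = [v for v in num.columns if miss[v].any()]
    for _ in range(sweeps):
        for var in order:
            mis_idx = miss[var]
            obs_idx = ~mis_idx
            X = _design(work, var)
            y_obs = work.loc[obs_idx, var].to_numpy(dtype=float)
            X_obs, X_mis = X[obs_idx.to_numpy()], X[mis_idx.to_numpy()]
            if binary[var]:
                if len(np.unique(y_obs)) < 2:
                    work.loc[mis_idx, var] = y_obs[0]
                    continue
                clf = LogisticRegression(max_iter=200, C=1e3)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(X_obs, y_obs)
                p = clf.predict_proba(X_mis)[:, 1]
                work.loc[mis_idx, var] = (rng.random(len(p)) < p).astype(float)
            else:
                reg = LinearRegression().fit(X_obs, y_obs)
                pred_obs = reg.predict(X_obs)
                pred_mis = reg.predict(X_mis)
                # PMM: draw from the nearest donors' observed values
                k = min(_PMM_DONORS, len(y_obs))
                d = np.abs(pred_obs[None, :] - pred_mis[:, None])
                donors = np.argpartition(d, k - 1, axis=1)[:, :k]
                pick = donors[np.arange(len(pred_mis)), rng.integers(0, k, len(pred_mis))]
                work.loc[mis_idx, var] = y_obs[pick]
    return work


def impute_covariates_mice(
    data: pd.DataFrame,
    m: int = 10,
    seed: int = 0,
    sweeps: int = _DEFAULT_SWEEPS,
    outcome_col: str = "y",
    exclude: tuple[str, ...] = (),
) -> ImputationSet:
    """Produce ``m`` completed copies of ``data`` by chained equations.

    ``outcome_col`` (and any ``exclude`` columns) are dropped from every
    conditional model and re-attached unchanged, so imputation ignores
    the outcome by construction.  Non-numeric columns are passed through
    untouched.  Deterministic for fixed ``seed``.
    """
    drop = [c for c in (outcome_col, *exclude) if c in data.columns]
    passthrough_cols = [
        c for c in data.columns
        if c in drop or not pd.api.types.is_numeric_dtype(data[c])
    ]
    num = data.drop(columns=passthrough_cols).astype(float)
    miss = num.isna()

    for var in num.columns:
        frac = miss[var].mean()
        if frac > 0.5:
            log.warning("variable %s is %.0f%% missing", var, 100 * frac)
        if miss[var].all():
            raise ValueError(f"variable {var!r} is entirely missing")

    binary = {v: _is_binary(num[v]) for v in num.columns}
    rng = np.random.default_rng(seed)

    if not miss.any().any():
        datasets = [data.copy() for _ in range(m)]
    else:
        datasets = []
        for _ in range(m):
            completed = _impute_once(num, miss, binary, sweeps, rng)
            full = data.copy()
            full[completed.columns] = completed
            datasets.append(full)

    mask = pd.DataFrame(False, index=data.index, columns=data.columns)
    mask[miss.columns] = miss
    return ImputationSet(datasets, mask)
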