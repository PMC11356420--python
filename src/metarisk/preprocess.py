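"""Metabolomics preprocessing: filtering, LOD imputation, truncation, QC loess.

The pipeline order is fixed: missingness filter -> half-minimum LOD
imputation -> (covariate multiple imputation, see :mod:`metarisk.mice`)
-> outlier truncation -> QC-anchored loess drift normalization.  The
loess step applies only to chromatography/MS-type platforms; NMR and the
lipid panel are left on their native scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .synthetic import FeatureMatrix

__all__ = [
    "PreprocessConfig",
    "QCSummary",
    "filter_missingness",
    "impute_half_min",
    "truncate_outliers",
    "loess_normalize",
    "qc_median_cv",
    "preprocess_platform",
]

log = logging.getLogger(__name__)

#: platforms whose run-order drift is removed with QC-anchored loess
LOESS_PLATFORMS = ("LC-MS", "GC-MS")


@dataclass
class PreprocessConfig:
    missing_threshold: float = 0.20
    iqr_multiplier: float = 3.0
    loess_span: float = 0.75
    n_imputations: int = 10
    imputation_seed: int = 0
    loess_platforms: tuple[str, ...] = LOESS_PLATFORMS

    def __post_init__(self) -> None:
        if not 0 < self.missing_threshold < 1:
            raise ValueError("missing_threshold must be in (0, 1)")
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be > 0")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        if self.n_imputations < 2:
            raise ValueError("need at least 2 imputations")


@dataclass
class QCSummary:
    """Per-platform replicate precision: median CV% over features."""

    platform: str
    median_cv_pct: float
    per_feature_cv_pct: pd.Series = field(repr=False, default=None)


def filter_missingness(matrix: FeatureMatrix, threshold: float = 0.20) -> FeatureMatrix:
    """Drop features whose missing fraction among study samples exceeds ``threshold``.

    The boundary is kept: a feature missing exactly ``threshold`` of study
    samples survives ("more than" is read strictly).  QC rows do not enter
    the denominator.  Column order is preserved.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    study = matrix.study
    feats = matrix.feature_columns
    miss_frac = study[feats].isna().mean(axis=0)
    keep = [f for f in feats if miss_frac[f] <= threshold]
    if not keep:
        raise ValueError(
            f"{matrix.platform}: all {len(feats)} features exceed "
            f"{threshold:.0%} missingness"
        )
    data = matrix.data[list(matrix.data.columns[:3]) + keep]
    return FeatureMatrix(matrix.platform, data, matrix.truth)


def impute_half_min(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace below-LOD (missing) entries by half the feature's minimum nonzero value.

    The minimum is taken over observed study-sample values; observed
    entries are untouched.  A feature with no nonzero observed value has
    no defined detection limit and raises.
    """
    data = matrix.data.copy()
    study_mask = data["is_qc"] == 0
    for feat in matrix.feature_columns:
        col = data[feat]
        if not col.isna().any():
            continue
        observed = col[study_mask & col.notna() & (col != 0)]
        if observed.empty:
            raise ValueError(f"feature {feat!r} has no nonzero observed value")
        data.loc[col.isna(), feat] = 0.5 * observed.min()
    return FeatureMatrix(matrix.platform, data, matrix.truth)


def truncate_outliers(
    values: pd.Series | np.ndarray, iqr_multiplier: float = 3.0
) -> pd.Series | np.ndarray:
    """Clip a numeric variable to [Q1 - k*IQR, Q3 + k*IQR] (k = 3 by default).

    Idempotent; a constant variable (IQR 0 and all values equal to the
    quartiles) passes through unchanged.  Quartiles use the linear
    interpolation convention.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size == 0:
        return values
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
    clipped = np.clip(arr, lo, hi)
    if isinstance(values, pd.Series):
        return pd.Series(clipped, index=values.index, name=values.name)
    return clipped


def truncate_matrix(matrix: FeatureMatrix, iqr_multiplier: float = 3.0) -> FeatureMatrix:
    """Apply :func:`truncate_outliers` feature-wise, bounds from study samples."""
    data = matrix.data.copy()
    study_mask = (data["is_qc"] == 0).to_numpy()
    for feat in matrix.feature_columns:
        col = data[feat].to_numpy(dtype=float, copy=True)
        finite = col[study_mask & ~np.isnan(col)]
        if finite.size == 0:
            continue
        q1, q3 = np.percentile(finite, [25, 75])
        iqr = q3 - q1
        col[study_mask] = np.clip(
            col[study_mask], q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
        )
        data[feat] = col
    return FeatureMatrix(matrix.platform, data, matrix.truth)


def _loess_curve(x: np.ndarray, y: np.ndarray, xnew: np.ndarray, span: float) -> np.ndarray:
    """Smooth y(x) with LOWESS (frac=span) and evaluate at xnew."""
    fitted = lowess(y, x, frac=span, it=1, xvals=xnew)
    return np.asarray(fitted, dtype=float)


def loess_normalize(
    matrix: FeatureMatrix, span: float = 0.75, min_qc: int = 4
) -> FeatureMatrix:
    """Remove run-order drift using the interspersed pooled-QC samples.

    Per batch and feature, a loess curve (span 0.75) of log QC intensity
    versus run order is fit; every sample's value is divided by the
    curve's prediction at its run order and rescaled by the batch QC
    median so units are preserved.  Batches with fewer than ``min_qc`` QC
    rows fall back to batch-median scaling (logged).
    """
    data = matrix.data.copy()
    feats = matrix.feature_columns
    vals = data[feats].to_numpy(dtype=float)
    log_vals = np.log(np.where(vals > 0, vals, np.nan))
    run = data["run_order"].to_numpy(dtype=float)
    is_qc = data["is_qc"].to_numpy() == 1

    for b in np.unique(data["batch"]):
        sel = (data["batch"] == b).to_numpy()
        qc_sel = sel & is_qc
        n_qc = int(qc_sel.sum())
        if n_qc == 0:
            continue
        qc_run = run[qc_sel]
        for j in range(len(feats)):
            y = log_vals[qc_sel, j]
            ok = ~np.isnan(y)
            med = np.nanmedian(y[ok]) if ok.any() else np.nan
            if np.isnan(med):
                continue
            if n_qc < min_qc or ok.sum() < min_qc:
                curve = np.full(int(sel.sum()), med)
                if j == 0:
                    log.info(
                        "%s batch %s: %d QC rows < %d, batch-median fallback",
                        matrix.platform, b, n_qc, min_qc,
                    )
            else:
                curve = _loess_curve(qc_run[ok], y[ok], run[sel], span)
                # guard against extrapolation artifacts at batch edges
                curve = np.where(np.isnan(curve), med, curve)
            log_vals[sel, j] = log_vals[sel, j] - curve + med
    out = np.exp(log_vals)
    out[np.isnan(vals)] = np.nan
    data[feats] = out
    return FeatureMatrix(matrix.platform, data, matrix.truth)


def qc_median_cv(
    matrix: FeatureMatrix, replicate_ids: list[str] | None = None
) -> QCSummary:
    """Median coefficient of variation (percent) over features, from replicates.

    ``replicate_ids`` selects designated replicate rows; by default all QC
    rows are used.  Per feature, CV% = 100 * SD / mean over the replicate
    rows (sample SD, ddof=1); features with non-positive mean are
    excluded (logged).
    """
    if replicate_ids is None:
        rep = matrix.qc
    else:
        rep = matrix.data.loc[replicate_ids]
    if len(rep) < 2:
        raise ValueError("need at least 2 replicate rows")
    feats = matrix.feature_columns
    vals = rep[feats].to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    ok = mean > 0
    if not ok.all():
        log.info("%s: excluding %d zero/negative-mean features from CV",
                 matrix.platform, int((~ok).sum()))
    cv = pd.Series(100.0 * sd[ok] / mean[ok], index=np.asarray(feats)[ok])
    return QCSummary(matrix.platform, float(cv.median()), cv)


def preprocess_platform(
    matrix: FeatureMatrix, config: PreprocessConfig | None = None
) -> FeatureMatrix:
    """Run the metabolite-side chain: filter -> half-min -> truncate -> loess."""
    config = config or PreprocessConfig()
    m = filter_missingness(matrix, config.missing_threshold)
    m = impute_half_min(m)
    m = truncate_matrix(m, config.iqr_multiplier)
    if matrix.platform in config.loess_platforms:
        m = loess_normalize(m, config.loess_span)
    return m
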