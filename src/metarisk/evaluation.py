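"""Honest performance assessment and study orchestration.

Six joint selection+prediction procedures are evaluated by repeated
(Monte-Carlo) stratified cross-validation: within every training fold
the variable-selection step is re-run from scratch, the predictor is fit
on the selected variables, and held-out samples are scored — selection
never sees evaluation data.  Per-imputation predictions are averaged
within a fold before the AUC is computed (Rubin-style averaging of
per-imputation AUCs is available as an alternative).

``run_study`` wires the whole pipeline together: synthetic cohort,
per-platform preprocessing, covariate multiple imputation, CV-AUC
reports per outcome x platform x feature set x procedure, stability
selection with cross-procedure and cross-platform unions, and PEV
reporting, plus the two sensitivity switches (hormone-therapy exclusion
and pooled-platform mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .learners import LearnerSpec, default_library, fast_library, with_screens
from .metrics import _safe_logistic, auc, compute_pev
from .mice import impute_covariates_mice
from .preprocess import PreprocessConfig, preprocess_platform, qc_median_cv
from .selection import (
    SelectionResult,
    lasso_select,
    sl_rank_select,
    stability_select,
    union_final,
)
from .super_learner import compute_vims, fit_super_learner, predict_sl
from .synthetic import (
    RISK_COVARIATES,
    CohortConfig,
    FeatureMatrix,
    generate_cohort,
)

__all__ = [
    "ProcedureSpec",
    "PROCEDURES",
    "CVAUCReport",
    "cv_evaluate",
    "StudyConfig",
    "StudyReport",
    "run_study",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProcedureSpec:
    """One of the six selection+prediction procedures."""

    name: str
    selector: str  # none | lasso | sl_rank
    predictor: str  # logistic | super_learner
    screens: bool = False

    def __post_init__(self) -> None:
        if self.selector not in ("none", "lasso", "sl_rank"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.predictor not in ("logistic", "super_learner"):
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.screens and self.selector != "none":
            raise ValueError("screens are only valid without a separate selector")


PROCEDURES: dict[str, ProcedureSpec] = {
    "SL": ProcedureSpec("SL", "none", "super_learner"),
    "SL_screens": ProcedureSpec("SL_screens", "none", "super_learner", screens=True),
    "lasso_GLM": ProcedureSpec("lasso_GLM", "lasso", "logistic"),
    "lasso_SL": ProcedureSpec("lasso_SL", "lasso", "super_learner"),
    "SL_GLM": ProcedureSpec("SL_GLM", "sl_rank", "logistic"),
    "SL_SL": ProcedureSpec("SL_SL", "sl_rank", "super_learner"),
}


@dataclass
class CVAUCReport:
    procedure: str
    feature_set: str
    aucs: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n: int
    leakage_overlap: int = 0  # audit: train/test row overlaps seen (must be 0)

    @classmethod
    def from_aucs(cls, procedure: str, feature_set: str, aucs: np.ndarray,
                  n: int, overlap: int = 0) -> "CVAUCReport":
        aucs = np.asarray(aucs, dtype=float)
        m = float(aucs.mean())
        se = float(aucs.std(ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0
        return cls(procedure, feature_set, aucs, m, m - 1.96 * se, m + 1.96 * se,
                   n, overlap)


def _select_variables(
    spec: ProcedureSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    forced: list[str],
    library: list[LearnerSpec],
    seed: int,
    k: int,
    sl_folds: int,
    lasso_folds: int,
    lasso_lambdas: int = 20,
    lasso_rule: str = "min",
) -> list[str]:
    if spec.selector == "none":
        return list(X.columns)
    if spec.selector == "lasso":
        return lasso_select(
            X, y, forced, seed=seed, n_folds=lasso_folds,
            n_lambdas=lasso_lambdas, lambda_rule=lasso_rule,
        ).selected
    fit = fit_super_learner(X, y, library, folds=sl_folds, seed=seed)
    return sl_rank_select(compute_vims(fit), k=k, forced_ids=forced).selected


def _fit_predict(
    spec: ProcedureSpec,
    Xtr: pd.DataFrame,
    ytr: np.ndarray,
    Xte: pd.DataFrame,
    library: list[LearnerSpec],
    seed: int,
    sl_folds: int,
) -> np.ndarray:
    if spec.predictor == "logistic":
        scaler = StandardScaler().fit(Xtr.to_numpy(dtype=float))
        clf = _safe_logistic(scaler.transform(Xtr.to_numpy(dtype=float)), ytr)
        return clf.predict_proba(scaler.transform(Xte.to_numpy(dtype=float)))[:, 1]
    fit = fit_super_learner(Xtr, ytr, library, folds=sl_folds, seed=seed)
    return predict_sl(fit, Xte)


def cv_evaluate(
    datasets: list[pd.DataFrame],
    spec: ProcedureSpec,
    forced: list[str],
    library: list[LearnerSpec] | None = None,
    reps: int = 100,
    folds: int = 5,
    seed: int = 0,
    k_select: int = 20,
    sl_folds: int = 10,
    lasso_folds: int = 10,
    lasso_lambdas: int = 20,
    lasso_rule: str = "min",
    outcome_col: str = "y",
    combine: str = "pool_predictions",
    feature_set: str = "",
) -> CVAUCReport:
    """Monte-Carlo cross-validated AUC of one selection+prediction procedure.

    ``datasets`` holds the m imputed copies of one analysis dataset (same
    rows, same outcome).  Per replication a fresh stratified ``folds``-fold
    partition is drawn; selection and prediction run inside each training
    fold per imputation, and per-imputation held-out predictions are
    averaged before the replication AUC is computed (``combine`` =
    ``"average_auc"`` instead averages per-imputation AUCs).
    """
    library = library or fast_library()
    if spec.screens:
        library = with_screens(library, k_select)
    y = datasets[0][outcome_col].to_numpy(dtype=int)
    features = [c for c in datasets[0].columns if c != outcome_col]
    n = len(y)
    rng = np.random.default_rng(seed)

    aucs = np.empty(reps)
    overlap_total = 0
    for rep in range(reps):
        part_seed = int(rng.integers(0, 2**31 - 1))
        splits = _draw_partition(y, folds, part_seed)
        pooled = np.zeros(n)
        per_imp_auc = []
        for i, df in enumerate(datasets):
            preds = np.empty(n)
            X = df[features]
            for tr, te in splits:
                overlap = len(np.intersect1d(tr, te))
                assert overlap == 0, "selection fold touched held-out rows"
                overlap_total += overlap
                fold_seed = (part_seed + 13 * i) % (2**31 - 1)
                sel = _select_variables(
                    spec, X.iloc[tr], y[tr], forced, library, fold_seed,
                    k_select, sl_folds, lasso_folds, lasso_lambdas, lasso_rule,
                )
                preds[te] = _fit_predict(
                    spec, X.iloc[tr][sel], y[tr], X.iloc[te][sel], library,
                    fold_seed, sl_folds,
                )
            pooled += preds / len(datasets)
            if combine == "average_auc":
                per_imp_auc.append(auc(preds, y))
        aucs[rep] = (
            float(np.mean(per_imp_auc)) if combine == "average_auc" else auc(pooled, y)
        )
    return CVAUCReport.from_aucs(spec.name, feature_set, aucs, n, overlap_total)


def _draw_partition(y: np.ndarray, folds: int, seed: int, max_tries: int = 10):
    """Stratified fold partition; redraw if any fold lacks a class."""
    for t in range(max_tries):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + t)
        splits = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[te])) == 2 for _, te in splits):
            if t > 0:
                log.info("partition redrawn %d time(s)", t)
            return splits
    raise RuntimeError("could not draw a partition with both classes in every fold")


# ---------------------------------------------------------------------------
# full study orchestration
# ---------------------------------------------------------------------------

FEATURE_SETS = ("covariates_only", "metabolites_base", "metabolites_all")


@dataclass
class StudyConfig:
    """Everything needed for an end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    outcomes: tuple[str, ...] = ("A", "B")
    platforms: tuple[str, ...] | None = None  # None = all generated
    feature_sets: tuple[str, ...] = FEATURE_SETS
    procedures: tuple[str, ...] = tuple(PROCEDURES)
    reps: int = 100
    cv_folds: int = 5
    sl_folds: int = 10
    lasso_folds: int = 10
    lasso_lambdas: int = 20
    lasso_rule: str = "min"  # lambda rule: "min" or "1se"
    n_imputations: int = 10
    library: str = "default"  # "default" | "fast"
    top_k: int = 20
    stability_threshold: float = 0.70
    exclude_ht: bool = False
    pooled: bool = False
    combine: str = "pool_predictions"
    seed: int = 0

    def make_library(self) -> list[LearnerSpec]:
        return default_library() if self.library == "default" else fast_library()


@dataclass
class StudyReport:
    cv_reports: dict  # (outcome, feature_set, platform, procedure) -> CVAUCReport
    stability: dict  # (outcome, platform, procedure) -> StabilityTable
    final_sets: dict  # outcome -> union_final output
    pev: dict  # outcome -> PEVReport
    qc: dict  # platform -> (pre, post) QCSummary
    n_rows: dict  # outcome -> analysis n


def _encode_covariates(frame: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate matrix: base design variables + risk factors.

    Race/ethnicity is recoded as binary indicators (reference level
    dropped), mirroring the usual treatment of categorical covariates.
    """
    out = frame[["age", "enrollment_date"]].astype(float).copy()
    race = pd.get_dummies(frame["race_ethnicity"], prefix="race", drop_first=True)
    out = pd.concat([out, race.astype(float)], axis=1)
    for c in RISK_COVARIATES:
        if c in frame.columns:
            out[c] = frame[c].astype(float)
    return out


def _base_columns(encoded: pd.DataFrame) -> list[str]:
    return ["age", "enrollment_date"] + [
        c for c in encoded.columns if c.startswith("race_")
    ]


def _log_features(matrix: FeatureMatrix, ids: pd.Index) -> pd.DataFrame:
    """Log-scale study-sample metabolite block aligned to participant ids."""
    study = matrix.study
    vals = study.loc[study.index.intersection(ids), matrix.feature_columns]
    return np.log(vals.clip(lower=1e-12))


def run_study(config: StudyConfig) -> StudyReport:
    """Generate, preprocess and evaluate a full synthetic study."""
    cohort, matrices = generate_cohort(config.cohort)
    if config.platforms is not None:
        matrices = [m for m in matrices if m.platform in config.platforms]

    if config.exclude_ht:
        keep = cohort.participants["ht_use"] != 1.0
        n_before = len(cohort.participants)
        cohort.participants = cohort.participants.loc[keep]
        log.info("HT exclusion: %d -> %d participants", n_before, int(keep.sum()))

    qc = {}
    processed: dict[str, FeatureMatrix] = {}
    for m in matrices:
        pre = qc_median_cv(m)
        pm = preprocess_platform(m, config.preprocess)
        processed[m.platform] = pm
        qc[m.platform] = (pre, qc_median_cv(pm))

    library = config.make_library()
    cv_reports: dict = {}
    stability: dict = {}
    final_sets: dict = {}
    pev: dict = {}
    n_rows: dict = {}

    for outcome in config.outcomes:
        frame = cohort.outcome_frame(outcome)
        n_rows[outcome] = len(frame)
        encoded = _encode_covariates(frame)
        encoded["y"] = frame["y"].to_numpy()
        imputed = impute_covariates_mice(
            encoded, m=config.n_imputations, seed=config.seed + 17,
        )
        base_cols = _base_columns(encoded)
        cov_cols = [c for c in encoded.columns if c != "y"]

        def datasets_for(platform: str | None, feature_set: str) -> list[pd.DataFrame]:
            out = []
            for df in imputed.datasets:
                if feature_set == "covariates_only":
                    out.append(df[cov_cols + ["y"]])
                    continue
                feats = _log_features(processed[platform], df.index)
                cols = base_cols if feature_set == "metabolites_base" else cov_cols
                joined = pd.concat([df[cols], feats.reindex(df.index)], axis=1)
                joined["y"] = df["y"].to_numpy()
                out.append(joined)
            return out

        # --- CV-AUC reports -------------------------------------------------
        for feature_set in config.feature_sets:
            plats = [None] if feature_set == "covariates_only" else list(processed)
            for platform in plats:
                data = datasets_for(platform, feature_set)
                for pname in config.procedures:
                    rep = cv_evaluate(
                        data,
                        PROCEDURES[pname],
                        forced=base_cols,
                        library=library,
                        reps=config.reps,
                        folds=config.cv_folds,
                        seed=config.seed + 101,
                        k_select=config.top_k,
                        sl_folds=config.sl_folds,
                        lasso_folds=config.lasso_folds,
                        lasso_lambdas=config.lasso_lambdas,
                        lasso_rule=config.lasso_rule,
                        combine=config.combine,
                        feature_set=feature_set,
                    )
                    cv_reports[(outcome, feature_set, platform, pname)] = rep

        # --- pooled-platform sensitivity mode (lasso + GLM only) ------------
        if config.pooled:
            pooled_sets = []
            for df in imputed.datasets:
                feats = pd.concat(
                    [_log_features(processed[p], df.index).reindex(df.index)
                     for p in processed],
                    axis=1,
                )
                joined = pd.concat([df[cov_cols], feats], axis=1)
                joined["y"] = df["y"].to_numpy()
                pooled_sets.append(joined)
            cv_reports[(outcome, "metabolites_all", "pooled", "lasso_GLM")] = (
                cv_evaluate(
                    pooled_sets,
                    PROCEDURES["lasso_GLM"],
                    forced=base_cols,
                    library=library,
                    reps=config.reps,
                    folds=config.cv_folds,
                    seed=config.seed + 211,
                    lasso_folds=config.lasso_folds,
                    lasso_lambdas=config.lasso_lambdas,
                    lasso_rule=config.lasso_rule,
                    combine=config.combine,
                    feature_set="metabolites_all",
                )
            )

        # --- final selection: stability over imputations, then unions -------
        stable_sets: dict[tuple[str, str], list[str]] = {}
        for platform in processed:
            data = datasets_for(platform, "metabolites_all")
            for proc in ("lasso", "sl_rank"):
                per_imp: list[SelectionResult] = []
                for i, df in enumerate(data):
                    X = df.drop(columns=["y"])
                    yv = df["y"].to_numpy(dtype=int)
                    if proc == "lasso":
                        res = lasso_select(
                            X, yv, base_cols, seed=config.seed + 3 * i,
                            n_folds=config.lasso_folds,
                            n_lambdas=max(config.lasso_lambdas, 30),
                            lambda_rule=config.lasso_rule,
                        )
                    else:
                        fit = fit_super_learner(
                            X, yv, library, folds=config.sl_folds,
                            seed=config.seed + 3 * i,
                        )
                        res = sl_rank_select(
                            compute_vims(fit), k=config.top_k, forced_ids=base_cols
                        )
                    res.imputation_index = i
                    res.platform = platform
                    per_imp.append(res)
                table = stability_select(per_imp, config.stability_threshold)
                stability[(outcome, platform, proc)] = table
                stable_sets[(platform, proc)] = table.final_set

        union = union_final(stable_sets, covariate_names=cov_cols)
        final_sets[outcome] = union

        selected = union["metabolites"] + union["covariates"]
        if selected:
            # PEV on the first completed dataset with all platform blocks
            df0 = imputed.datasets[0]
            feats = pd.concat(
                [_log_features(processed[p], df0.index).reindex(df0.index)
                 for p in processed],
                axis=1,
            )
            pev_data = pd.concat([df0[cov_cols], feats], axis=1)
            pev_data["y"] = df0["y"].to_numpy()
            pev[outcome] = compute_pev(
                selected, pev_data, base_cols, folds=config.cv_folds,
                seed=config.seed + 5,
            )

    return StudyReport(cv_reports, stability, final_sets, pev, qc, n_rows)
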