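"""Synthetic matched case-control cohorts with multi-platform metabolite blocks.

Emulates the structure of a nested case-control metabolomics study in a
cohort of post-menopausal women: two cancer outcomes (A, breast-like;
B, colorectal-like) sharing one control group, 1:1 matching on age,
enrollment date and race/ethnicity, and four measurement platforms whose
feature matrices carry batch structure, run-order drift, interspersed
pooled QC samples and below-limit-of-detection (LOD) censoring.

A sparse true metabolite signal is planted for one outcome (default B)
and the other outcome's metabolite signal is null, so downstream
selection and prediction stages can be validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "CohortConfig",
    "CohortTable",
    "FeatureMatrix",
    "MatchRule",
    "MatchingError",
    "generate_cohort",
    "match_controls",
]

#: metadata columns that precede feature columns in every platform table
META_COLUMNS = ("sample_id", "batch", "run_order", "is_qc")

#: risk-factor covariates generated beyond the base (design) covariates
RISK_COVARIATES = (
    "bmi",
    "waist",
    "alcohol",
    "calcium",
    "folate",
    "red_meat",
    "energy_expenditure",
    "smoking",
    "colonoscopy",
    "polyp_removal",
    "ht_use",
)

BASE_COVARIATES = ("age", "enrollment_date", "race_ethnicity")

_INFEASIBLE = 1e9


class MatchingError(RuntimeError):
    """Raised when no feasible 1:1 matching exists; names the stratum."""


@dataclass(frozen=True)
class MatchRule:
    """Matching tolerances for the nested case-control design.

    Cases and controls must agree on race/ethnicity exactly, on age within
    ``age_tolerance`` years and on enrollment date within
    ``enrollment_tolerance`` months.
    """

    age_tolerance: float = 2.0
    enrollment_tolerance: float = 2.0
    exact_on: str = "race_ethnicity"

    def __post_init__(self) -> None:
        if self.age_tolerance <= 0 or self.enrollment_tolerance <= 0:
            raise ValueError("matching tolerances must be positive")

    def distance(self, age_gap: float, enroll_gap: float) -> float:
        """Tolerance-scaled matching distance |age|/tol_a + |enroll|/tol_e."""
        return abs(age_gap) / self.age_tolerance + abs(enroll_gap) / self.enrollment_tolerance

    def feasible(self, age_gap: float, enroll_gap: float) -> bool:
        return (
            abs(age_gap) <= self.age_tolerance
            and abs(enroll_gap) <= self.enrollment_tolerance
        )


def _default_platform_sizes() -> dict[str, int]:
    return {"LC-MS": 150, "lipid": 687, "NMR": 59, "GC-MS": 107}


def _default_missing_rates() -> dict[str, float]:
    # per-variable fraction missing; base covariates are complete by design
    return {
        "bmi": 0.008,
        "waist": 0.008,
        "smoking": 0.008,
        "energy_expenditure": 0.06,
        "alcohol": 0.025,
        "calcium": 0.025,
        "folate": 0.025,
        "red_meat": 0.025,
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic study.

    Defaults mirror the motivating study design: 577 cases of outcome A,
    181 of outcome B, 758 shared controls, and four platforms with
    150 / 687 / 59 / 107 detected features.  ``effect_size`` is the
    log-scale mean shift (in units of the feature's total SD) planted in
    ``n_signal_features`` metabolites of ``signal_platform`` for cases of
    ``signal_outcome``; the other outcome's metabolite signal is null.
    """

    n_cases_A: int = 577
    n_cases_B: int = 181
    n_controls: int = 758
    platform_sizes: Mapping[str, int] = field(default_factory=_default_platform_sizes)
    n_signal_features: int = 10
    effect_size: float = 0.5
    signal_outcome: str = "B"
    signal_platform: str | None = None  # defaults to first platform
    covariate_missing_rates: Mapping[str, float] = field(
        default_factory=_default_missing_rates
    )
    lod_missing_rate: float = 0.08
    heavy_missing_frac: float = 0.0  # fraction of features censored >20%
    n_batches: int = 8
    qc_every: int = 9
    drift_amplitude: float = 0.3
    drift_profile: str = "random"  # "random" quadratic or deterministic "linear"
    noise_sd: float = 0.2
    biological_sd_range: tuple[float, float] = (0.3, 0.8)
    control_pool_factor: float = 1.0  # eligible controls per case beyond 1:1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases_A", "n_cases_B", "n_controls", "n_batches", "qc_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_controls < self.n_cases_A + self.n_cases_B:
            raise ValueError(
                "1:1 matching needs at least as many controls as total cases"
            )
        for name in ("lod_missing_rate", "heavy_missing_frac"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for var, rate in self.covariate_missing_rates.items():
            if not 0 <= rate < 1:
                raise ValueError(f"missing rate for {var} must be in [0, 1)")
        sizes = dict(self.platform_sizes)
        if len(sizes) != len(self.platform_sizes):
            raise ValueError("platform names must be unique")
        if any(p <= 0 for p in sizes.values()):
            raise ValueError("platform feature counts must be > 0")
        if self.signal_outcome not in ("A", "B"):
            raise ValueError("signal_outcome must be 'A' or 'B'")
        if self.signal_platform is None:
            object.__setattr__(self, "signal_platform", next(iter(sizes)))
        elif self.signal_platform not in sizes:
            raise ValueError(f"unknown signal_platform {self.signal_platform!r}")


@dataclass
class CohortTable:
    """Participant-level table: design variables, risk factors, case status."""

    participants: pd.DataFrame

    @property
    def case_ids(self) -> pd.Index:
        return self.participants.index[self.participants["case_status"] != "control"]

    @property
    def control_ids(self) -> pd.Index:
        return self.participants.index[self.participants["case_status"] == "control"]

    def outcome_frame(self, outcome: str) -> pd.DataFrame:
        """Cases of one outcome plus all controls, with binary ``y`` column."""
        status = self.participants["case_status"]
        keep = (status == "control") | (status == f"case_{outcome}")
        sub = self.participants.loc[keep].copy()
        sub["y"] = (sub["case_status"] == f"case_{outcome}").astype(int)
        return sub


@dataclass
class FeatureMatrix:
    """One platform's samples-by-features table with run metadata.

    ``data`` is indexed by sample id with columns ``batch``, ``run_order``,
    ``is_qc`` followed by feature columns; missing abundances (below LOD)
    are NaN.  ``truth`` is the generator-only sidecar listing planted
    signal features and their effects; it never feeds the analysis path.
    """

    platform: str
    data: pd.DataFrame
    truth: pd.DataFrame | None = None

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def study(self) -> pd.DataFrame:
        """Rows for biological study samples (QC rows excluded)."""
        return self.data.loc[self.data["is_qc"] == 0]

    @property
    def qc(self) -> pd.DataFrame:
        return self.data.loc[self.data["is_qc"] == 1]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.platform, self.data.copy(), self.truth)


# ---------------------------------------------------------------------------
# cohort table generation
# ---------------------------------------------------------------------------

_RACE_LEVELS = np.array(["white", "black", "hispanic", "asian", "other"])
_RACE_PROBS = np.array([0.70, 0.13, 0.08, 0.05, 0.04])

# per-outcome log-odds-like mean shifts applied to case covariates so that
# covariate-only prediction is informative (AUC in the high 0.5s, matching
# the modest discrimination typical of lifestyle risk factors)
_CASE_SHIFTS = {
    "A": {"bmi": 1.2, "waist": 3.0, "alcohol": 0.45, "folate": 45.0, "smoking": 0.02},
    "B": {"bmi": 1.3, "waist": 3.5, "alcohol": 0.25, "folate": 35.0, "smoking": 0.03,
          "colonoscopy": -0.10, "polyp_removal": -0.04},
}


def _draw_risk_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Control-distribution risk factors, orders of magnitude per the field."""
    out = pd.DataFrame(
        {
            "bmi": rng.normal(28.0, 5.5, n).clip(16, 55),
            "waist": rng.normal(86.0, 12.5, n).clip(55, 150),
            "alcohol": rng.gamma(0.8, 1.6, n),  # servings/week, zero-inflated-ish
            "calcium": rng.normal(1050.0, 420.0, n).clip(50, None),
            "folate": rng.normal(620.0, 260.0, n).clip(40, None),
            "red_meat": rng.gamma(2.2, 0.9, n),
            "energy_expenditure": rng.gamma(1.4, 7.0, n),
            "smoking": (rng.random(n) < 0.065).astype(float),
            "colonoscopy": (rng.random(n) < 0.47).astype(float),
            "polyp_removal": (rng.random(n) < 0.095).astype(float),
            "ht_use": (rng.random(n) < 0.40).astype(float),
        }
    )
    return out


def _apply_case_shifts(rng: np.random.Generator, df: pd.DataFrame, outcome: str) -> None:
    for var, shift in _CASE_SHIFTS[outcome].items():
        if df[var].dropna().isin([0.0, 1.0]).all():
            # binary: shift the prevalence
            p = df[var].mean() + shift
            df[var] = (rng.random(len(df)) < np.clip(p, 0.01, 0.99)).astype(float)
        else:
            df[var] = df[var] + shift


def _build_participants(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_cases = cfg.n_cases_A + cfg.n_cases_B
    statuses = ["case_A"] * cfg.n_cases_A + ["case_B"] * cfg.n_cases_B

    # cases first; each case's matched control inherits its matching keys
    case_age = rng.uniform(52, 78, n_cases).round(1)
    case_enroll = rng.integers(0, 60, n_cases).astype(float)  # months from origin
    case_race = rng.choice(_RACE_LEVELS, size=n_cases, p=_RACE_PROBS)

    frames = []
    for i, outcome in enumerate(("A", "B")):
        sel = np.array(statuses) == f"case_{outcome}"
        cov = _draw_risk_covariates(rng, int(sel.sum()))
        _apply_case_shifts(rng, cov, outcome)
        cov.insert(0, "race_ethnicity", case_race[sel])
        cov.insert(0, "enrollment_date", case_enroll[sel])
        cov.insert(0, "age", case_age[sel])
        cov.insert(0, "case_status", f"case_{outcome}")
        frames.append(cov)
    cases = pd.concat(frames, ignore_index=True)

    # matched controls: jitter keys within the matching tolerances
    n_matched = n_cases
    ctrl_cov = _draw_risk_covariates(rng, cfg.n_controls)
    ctrl_age = np.empty(cfg.n_controls)
    ctrl_enroll = np.empty(cfg.n_controls)
    ctrl_race = np.empty(cfg.n_controls, dtype=object)
    ctrl_age[:n_matched] = (
        cases["age"].to_numpy()[:n_matched] + rng.uniform(-1.8, 1.8, n_matched)
    ).round(1)
    ctrl_enroll[:n_matched] = np.clip(
        cases["enrollment_date"].to_numpy()[:n_matched]
        + rng.integers(-2, 3, n_matched),
        0,
        None,
    )
    ctrl_race[:n_matched] = cases["race_ethnicity"].to_numpy()[:n_matched]
    n_extra = cfg.n_controls - n_matched
    if n_extra > 0:
        ctrl_age[n_matched:] = rng.uniform(52, 78, n_extra).round(1)
        ctrl_enroll[n_matched:] = rng.integers(0, 60, n_extra).astype(float)
        ctrl_race[n_matched:] = rng.choice(_RACE_LEVELS, size=n_extra, p=_RACE_PROBS)
    ctrl_cov.insert(0, "race_ethnicity", ctrl_race)
    ctrl_cov.insert(0, "enrollment_date", ctrl_enroll)
    ctrl_cov.insert(0, "age", ctrl_age.round(1))
    ctrl_cov.insert(0, "case_status", "control")

    tab = pd.concat([cases, ctrl_cov], ignore_index=True)
    tab.index = pd.Index(
        [f"P{i:05d}" for i in range(1, len(tab) + 1)], name="participant_id"
    )

    # covariate missingness (MCAR at configured per-variable rates)
    for var, rate in cfg.covariate_missing_rates.items():
        if rate > 0 and var in tab.columns:
            mask = rng.random(len(tab)) < rate
            tab.loc[mask, var] = np.nan
    return tab


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_controls(cohort: CohortTable, rule: MatchRule | None = None) -> pd.DataFrame:
    """Optimal 1:1 case-control assignment within matching constraints.

    Within each race/ethnicity stratum, solves the bipartite assignment
    minimizing the total tolerance-scaled distance over all feasible
    pairings (Hungarian algorithm); infeasible pairs are excluded.

    Returns a frame indexed by case id with columns ``control_id`` and
    ``distance``.  Raises :class:`MatchingError` naming the stratum when
    some case cannot be matched.
    """
    rule = rule or MatchRule()
    tab = cohort.participants
    cases = tab.loc[tab["case_status"] != "control"]
    controls = tab.loc[tab["case_status"] == "control"]

    rows: list[tuple[str, str, float]] = []
    for stratum, case_sub in cases.groupby(rule.exact_on, sort=True):
        ctrl_sub = controls.loc[controls[rule.exact_on] == stratum]
        if len(ctrl_sub) < len(case_sub):
            raise MatchingError(
                f"stratum {stratum!r}: {len(case_sub)} cases but only "
                f"{len(ctrl_sub)} eligible controls"
            )
        age_gap = (
            case_sub["age"].to_numpy()[:, None] - ctrl_sub["age"].to_numpy()[None, :]
        )
        enr_gap = (
            case_sub["enrollment_date"].to_numpy()[:, None]
            - ctrl_sub["enrollment_date"].to_numpy()[None, :]
        )
        cost = np.abs(age_gap) / rule.age_tolerance + np.abs(enr_gap) / rule.enrollment_tolerance
        feasible = (np.abs(age_gap) <= rule.age_tolerance) & (
            np.abs(enr_gap) <= rule.enrollment_tolerance
        )
        cost = np.where(feasible, cost, _INFEASIBLE)
        ri, ci = linear_sum_assignment(cost)
        bad = cost[ri, ci] >= _INFEASIBLE
        if bad.any():
            unmatched = list(case_sub.index[ri[bad]])
            raise MatchingError(
                f"stratum {stratum!r}: no feasible control for cases {unmatched}"
            )
        for r, c in zip(ri, ci):
            rows.append((case_sub.index[r], ctrl_sub.index[c], float(cost[r, c])))

    out = pd.DataFrame(rows, columns=["case_id", "control_id", "distance"])
    return out.set_index("case_id")


# ---------------------------------------------------------------------------
# metabolite platform generation
# ---------------------------------------------------------------------------

def _batch_drift(
    cfg: CohortConfig, rng: np.random.Generator, t: np.ndarray
) -> np.ndarray:
    """Log-scale drift curve over scaled run order t in [-1, 1]."""
    if cfg.drift_profile == "linear":
        # deterministic monotone drift spanning exp(amplitude) fold-change
        return cfg.drift_amplitude * (t + 1.0) / 2.0
    c1, c2 = rng.normal(0.0, 1.0, 2)
    return cfg.drift_amplitude * (c1 * t + c2 * (t**2 - 1.0 / 3.0)) / 2.0


def _generate_platform(
    cfg: CohortConfig,
    rng: np.random.Generator,
    platform: str,
    n_features: int,
    participants: pd.DataFrame,
) -> FeatureMatrix:
    ids = participants.index.to_numpy()
    n = len(ids)
    status = participants["case_status"].to_numpy()

    # acquisition order: random permutation of study samples, then QC rows
    # inserted every qc_every study injections
    order = rng.permutation(n)
    sample_ids: list[str] = []
    is_qc: list[int] = []
    qc_count = 0
    for k, idx in enumerate(order):
        if k % cfg.qc_every == 0:
            qc_count += 1
            sample_ids.append(f"QC_{platform}_{qc_count:03d}")
            is_qc.append(1)
        sample_ids.append(ids[idx])
        is_qc.append(0)
    n_rows = len(sample_ids)
    run_order = np.arange(1, n_rows + 1)
    batch = np.minimum(
        (np.arange(n_rows) * cfg.n_batches) // n_rows, cfg.n_batches - 1
    ) + 1

    feat_names = [f"{platform}_m{j + 1:04d}" for j in range(n_features)]
    mu = rng.normal(10.0, 1.5, n_features)
    bio_sd = rng.uniform(*cfg.biological_sd_range, n_features)
    total_sd = np.sqrt(bio_sd**2 + cfg.noise_sd**2)

    # planted signal
    truth = None
    shift = np.zeros(n_features)
    if platform == cfg.signal_platform and cfg.n_signal_features > 0:
        sig_idx = rng.choice(n_features, size=min(cfg.n_signal_features, n_features),
                             replace=False)
        shift[sig_idx] = cfg.effect_size * total_sd[sig_idx]
        truth = pd.DataFrame(
            {
                "feature": [feat_names[j] for j in np.sort(sig_idx)],
                "outcome": cfg.signal_outcome,
                "log_mean_shift": shift[np.sort(sig_idx)],
                "effect_size_sd": cfg.effect_size,
            }
        )

    is_qc_arr = np.asarray(is_qc)
    is_case_sig = np.zeros(n_rows, dtype=bool)
    study_pos = np.where(is_qc_arr == 0)[0]
    is_case_sig[study_pos] = status[order] == f"case_{cfg.signal_outcome}"

    log_x = np.tile(mu, (n_rows, 1))
    # biological variation only for study samples (QC rows are a pooled sample)
    log_x[study_pos] += rng.normal(0.0, 1.0, (len(study_pos), n_features)) * bio_sd
    log_x[is_case_sig] += shift
    # batch drift, smooth in run order within each batch, shared across features
    for b in np.unique(batch):
        sel = batch == b
        r = run_order[sel].astype(float)
        t = 2.0 * (r - r.min()) / max(r.max() - r.min(), 1.0) - 1.0
        log_x[sel] += _batch_drift(cfg, rng, t)[:, None]
    log_x += rng.normal(0.0, cfg.noise_sd, (n_rows, n_features))
    values = np.exp(log_x)

    # LOD censoring: per-feature lower-quantile truncation among study samples
    rate = np.zeros(n_features)
    if cfg.lod_missing_rate > 0 or cfg.heavy_missing_frac > 0:
        rate = rng.uniform(0.0, 2.0 * cfg.lod_missing_rate, n_features)
        if cfg.heavy_missing_frac > 0:
            heavy = rng.random(n_features) < cfg.heavy_missing_frac
            rate[heavy] = rng.uniform(0.25, 0.40, int(heavy.sum()))
    if platform == "NMR":
        rate[:] = 0.0
    for j in np.where(rate > 0)[0]:
        col = values[study_pos, j]
        lod = np.quantile(col, rate[j])
        censored = study_pos[col < lod]
        values[censored, j] = np.nan

    data = pd.DataFrame(values, columns=feat_names)
    data.insert(0, "is_qc", is_qc_arr)
    data.insert(0, "run_order", run_order)
    data.insert(0, "batch", batch)
    data.index = pd.Index(sample_ids, name="sample_id")
    return FeatureMatrix(platform, data, truth)


def generate_cohort(config: CohortConfig) -> tuple[CohortTable, list[FeatureMatrix]]:
    """Generate a full synthetic study: cohort table plus one matrix per platform.

    Deterministic for a fixed ``config.seed``.  The returned cohort includes
    a ``matched_control_id`` column on case rows derived by optimal
    assignment under the default :class:`MatchRule`.
    """
    rng = np.random.default_rng(config.seed)
    participants = _build_participants(config, rng)
    cohort = CohortTable(participants)

    pairing = match_controls(cohort)
    participants["matched_control_id"] = pd.NA
    participants.loc[pairing.index, "matched_control_id"] = pairing["control_id"]

    matrices = [
        _generate_platform(config, rng, platform, int(p), participants)
        for platform, p in config.platform_sizes.items()
    ]
    return cohort, matrices
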