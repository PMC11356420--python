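"""Generator: matching optimality, planted-signal truth, determinism."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from metarisk import (
    CohortConfig,
    CohortTable,
    MatchRule,
    MatchingError,
    auc,
    generate_cohort,
    match_controls,
    qc_median_cv,
)


def _mini_cohort(case_rows, control_rows):
    rows = []
    for i, (age, enr, race) in enumerate(case_rows):
        rows.append((f"case{i}", "case_B", age, enr, race))
    for i, (age, enr, race) in enumerate(control_rows):
        rows.append((f"ctrl{i}", "control", age, enr, race))
    df = pd.DataFrame(
        rows, columns=["participant_id", "case_status", "age", "enrollment_date",
                       "race_ethnicity"]
    ).set_index("participant_id")
    return CohortTable(df)


class TestMatching:
    def test_single_feasible_pair(self):
        cohort = _mini_cohort([(60, 10, "w")], [(61, 10, "w")])
        pairing = match_controls(cohort)
        assert pairing.loc["case0", "control_id"] == "ctrl0"

    def test_tolerance_forces_farther_control(self):
        # the 63-year-old violates the 2-year rule, so the 59-year-old wins
        cohort = _mini_cohort([(60, 10, "w")], [(63, 10, "w"), (59, 10, "w")])
        pairing = match_controls(cohort)
        assert pairing.loc["case0", "control_id"] == "ctrl1"

    def test_infeasible_names_stratum(self):
        cohort = _mini_cohort([(60, 10, "w")], [(70, 10, "w")])
        with pytest.raises(MatchingError, match="'w'"):
            match_controls(cohort)

    def test_too_few_controls_in_stratum(self):
        cohort = _mini_cohort([(60, 10, "w"), (61, 10, "w")], [(60, 10, "w")])
        with pytest.raises(MatchingError, match="'w'"):
            match_controls(cohort)

    def test_matches_exhaustive_assignment_optimum(self, rng):
        """5 cases x 8 controls: total distance equals the enumeration optimum."""
        rule = MatchRule()
        for trial in range(3):
            case_age = rng.uniform(55, 75, 5).round(1)
            case_enr = rng.integers(0, 40, 5).astype(float)
            ctrl_age = np.concatenate([case_age + rng.uniform(-1.5, 1.5, 5),
                                       rng.uniform(55, 75, 3)]).round(1)
            ctrl_enr = np.concatenate([case_enr + rng.integers(-2, 3, 5),
                                       rng.integers(0, 40, 3)]).astype(float)
            cohort = _mini_cohort(
                [(a, e, "w") for a, e in zip(case_age, case_enr)],
                [(a, e, "w") for a, e in zip(ctrl_age, ctrl_enr)],
            )
            pairing = match_controls(cohort, rule)

            best = np.inf
            for perm in itertools.permutations(range(8), 5):
                total = 0.0
                for ci, ki in enumerate(perm):
                    da = case_age[ci] - ctrl_age[ki]
                    de = case_enr[ci] - ctrl_enr[ki]
                    if not rule.feasible(da, de):
                        total = np.inf
                        break
                    total += rule.distance(da, de)
                best = min(best, total)
            assert pairing["distance"].sum() == pytest.approx(best, abs=1e-9)

    def test_generated_pairing_passes_independent_rule_check(self, small_cohort):
        _, cohort, _ = small_cohort
        rule = MatchRule()
        tab = cohort.participants
        cases = tab[tab["case_status"] != "control"]
        assert cases["matched_control_id"].notna().all()
        # 1:1 - no control reused
        assert cases["matched_control_id"].is_unique
        for cid, row in cases.iterrows():
            ctrl = tab.loc[row["matched_control_id"]]
            assert ctrl["case_status"] == "control"
            assert abs(row["age"] - ctrl["age"]) <= rule.age_tolerance
            assert (
                abs(row["enrollment_date"] - ctrl["enrollment_date"])
                <= rule.enrollment_tolerance
            )
            assert row["race_ethnicity"] == ctrl["race_ethnicity"]


class TestGenerator:
    def test_default_design_counts(self):
        """Default configuration carries the motivating study's dimensions."""
        cfg = CohortConfig(seed=1)
        cohort, mats = generate_cohort(cfg)
        status = cohort.participants["case_status"].value_counts()
        assert status["case_A"] == 577
        assert status["case_B"] == 181
        assert status["control"] == 758
        sizes = {m.platform: len(m.feature_columns) for m in mats}
        assert sizes == {"LC-MS": 150, "lipid": 687, "NMR": 59, "GC-MS": 107}

    def test_fixed_seed_byte_identical(self):
        cfg = dict(n_cases_A=25, n_cases_B=20, n_controls=50,
                   platform_sizes={"LC-MS": 12}, seed=3)
        c1, m1 = generate_cohort(CohortConfig(**cfg))
        c2, m2 = generate_cohort(CohortConfig(**cfg))
        assert c1.participants.to_csv() == c2.participants.to_csv()
        assert m1[0].data.to_csv() == m2[0].data.to_csv()

    def test_zero_lod_rate_means_no_missing(self):
        cfg = CohortConfig(n_cases_A=20, n_cases_B=20, n_controls=40,
                           platform_sizes={"LC-MS": 15}, lod_missing_rate=0.0,
                           seed=4)
        _, mats = generate_cohort(cfg)
        assert not mats[0].data[mats[0].feature_columns].isna().any().any()

    def test_qc_structure_and_missingness_rates(self, small_cohort):
        cfg, cohort, mats = small_cohort
        m = mats[0]
        # QC rows appear every qc_every study rows
        study_seen = 0
        for _, row in m.data.iterrows():
            if row["is_qc"] == 1:
                assert study_seen % cfg.qc_every == 0
            else:
                study_seen += 1
        # configured covariate missingness within sampling error
        tab = cohort.participants
        for var, rate in cfg.covariate_missing_rates.items():
            observed = tab[var].isna().mean()
            se = np.sqrt(rate * (1 - rate) / len(tab)) + 1e-9
            assert abs(observed - rate) < 4 * se + 0.01

    def test_qc_cv_increases_with_noise(self):
        cvs = []
        for noise in (0.05, 0.15, 0.30):
            cfg = CohortConfig(n_cases_A=30, n_cases_B=30, n_controls=60,
                               platform_sizes={"LC-MS": 40}, noise_sd=noise,
                               drift_amplitude=0.0, seed=11)
            _, mats = generate_cohort(cfg)
            cvs.append(qc_median_cv(mats[0]).median_cv_pct)
        assert cvs[0] < cvs[1] < cvs[2]


class TestPlantedSignal:
    def test_null_effect_gives_null_single_feature_auc(self):
        cfg = CohortConfig(n_cases_A=5, n_cases_B=250, n_controls=260,
                           platform_sizes={"LC-MS": 6}, effect_size=0.0,
                           n_signal_features=1, drift_amplitude=0.0,
                           lod_missing_rate=0.0, seed=5)
        cohort, mats = generate_cohort(cfg)
        frame = cohort.outcome_frame("B")
        worst_dev = 0.0
        vals = mats[0].study
        for feat in mats[0].feature_columns:
            a = auc(np.log(vals.loc[frame.index, feat]), frame["y"])
            worst_dev = max(worst_dev, abs(a - 0.5))
        assert worst_dev < 0.07  # Monte-Carlo null band at n=510

    def test_one_sd_effect_matches_binormal_auc(self):
        """Single feature, 1-SD log-scale shift: AUC ~ Phi(1/sqrt(2)) ~ 0.76."""
        cfg = CohortConfig(n_cases_A=5, n_cases_B=1000, n_controls=1010,
                           platform_sizes={"LC-MS": 3}, effect_size=1.0,
                           n_signal_features=1, drift_amplitude=0.0,
                           lod_missing_rate=0.0, seed=6)
        cohort, mats = generate_cohort(cfg)
        feat = mats[0].truth["feature"].iloc[0]
        frame = cohort.outcome_frame("B")
        observed = auc(np.log(mats[0].study.loc[frame.index, feat]), frame["y"])
        assert observed == pytest.approx(norm.cdf(1 / np.sqrt(2)), abs=0.025)

    def test_truth_sidecar_only_on_signal_platform(self, small_cohort):
        cfg, _, mats = small_cohort
        assert mats[0].truth is not None
        assert len(mats[0].truth) == cfg.n_signal_features
        assert mats[1].truth is None
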