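"""Preprocessing: exact rules, loess efficacy, chain idempotence."""

import numpy as np
import pandas as pd
import pytest

from metarisk import (
    CohortConfig,
    FeatureMatrix,
    PreprocessConfig,
    filter_missingness,
    generate_cohort,
    impute_half_min,
    loess_normalize,
    preprocess_platform,
    qc_median_cv,
    truncate_outliers,
)
from metarisk.preprocess import truncate_matrix


def make_matrix(columns: dict, is_qc=None, platform="LC-MS") -> FeatureMatrix:
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(columns, dtype=float)
    df.insert(0, "is_qc", is_qc if is_qc is not None else np.zeros(n, dtype=int))
    df.insert(0, "run_order", np.arange(1, n + 1))
    df.insert(0, "batch", np.ones(n, dtype=int))
    df.index = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    return FeatureMatrix(platform, df)


class TestFilterMissingness:
    def test_above_threshold_dropped(self):
        m = make_matrix({"f": [1.0] * 7 + [np.nan] * 3,  # 30% missing
                         "g": [1.0] * 10})
        out = filter_missingness(m, 0.20)
        assert out.feature_columns == ["g"]

    def test_boundary_kept(self):
        m = make_matrix({"f": [1.0] * 8 + [np.nan] * 2})  # exactly 20%
        out = filter_missingness(m, 0.20)
        assert "f" in out.feature_columns

    def test_qc_rows_excluded_from_denominator(self):
        # 2 of 8 study rows missing (25% > 20%); QC rows complete
        col = [1.0, 1.0] + [1.0] * 6 + [np.nan, np.nan]
        is_qc = [1, 1] + [0] * 8
        m = make_matrix({"f": col, "g": [1.0] * 10}, is_qc=is_qc)
        assert "f" not in filter_missingness(m, 0.20).feature_columns

    def test_all_features_removed_raises(self):
        m = make_matrix({"f": [np.nan] * 8 + [1.0, 1.0]})
        with pytest.raises(ValueError, match="all"):
            filter_missingness(m, 0.20)

    def test_matches_bruteforce_recount(self, rng):
        cols = {}
        for j in range(50):
            v = rng.lognormal(1, 1, 40)
            k = rng.integers(0, 15)
            v[rng.choice(40, k, replace=False)] = np.nan
            cols[f"f{j}"] = v
        m = make_matrix(cols)
        kept = set(filter_missingness(m, 0.20).feature_columns)
        expected = {
            name for name, v in cols.items()
            if np.isnan(v).sum() / 40 <= 0.20
        }
        assert kept == expected
        # column order preserved
        assert filter_missingness(m, 0.20).feature_columns == [
            f for f in m.feature_columns if f in expected
        ]


class TestHalfMinImputation:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([4.0, 2.0, np.nan], [4.0, 2.0, 1.0]),
            ([0.0, 3.0, np.nan, 6.0], [0.0, 3.0, 1.5, 6.0]),  # min NONZERO is 3
            ([5.0, 2.5, 7.0], [5.0, 2.5, 7.0]),  # no missing: identity
        ],
    )
    def test_rule(self, column, expected):
        out = impute_half_min(make_matrix({"f": column}))
        np.testing.assert_allclose(out.data["f"].to_numpy(), expected)

    def test_all_zero_feature_raises(self):
        with pytest.raises(ValueError, match="f"):
            impute_half_min(make_matrix({"f": [0.0, 0.0, np.nan]}))

    def test_observed_entries_untouched(self, rng):
        v = rng.lognormal(0, 1, 30)
        v[rng.choice(30, 5, replace=False)] = np.nan
        m = make_matrix({"f": v})
        out = impute_half_min(m)
        obs = ~np.isnan(v)
        np.testing.assert_array_equal(out.data["f"].to_numpy()[obs], v[obs])
        assert not out.data["f"].isna().any()


class TestTruncation:
    def test_forced_clipping_values(self):
        # Q1=10, Q3=20 => bounds [-20, 50]
        base = np.repeat([10.0, 20.0], 50)
        vals = np.concatenate([base, [60.0, -25.0]])
        out = truncate_outliers(vals)
        assert out[-2] == pytest.approx(50.0)
        assert out[-1] == pytest.approx(-20.0)

    def test_identity_inside_bounds(self, rng):
        v = rng.normal(0, 1, 100)
        np.testing.assert_array_equal(truncate_outliers(v), v)

    def test_idempotent_and_never_increases_distance_to_median(self, rng):
        v = rng.standard_cauchy(500)
        once = truncate_outliers(v)
        np.testing.assert_allclose(truncate_outliers(once), once)
        med = np.median(v)
        assert (np.abs(once - med) <= np.abs(v - med) + 1e-12).all()

    def test_matches_alternative_quantile_oracle(self, rng):
        """Independent clip using a second quantile convention stays close."""
        v = rng.lognormal(0, 2, 400)
        ours = truncate_outliers(v)
        q1, q3 = np.quantile(v, [0.25, 0.75], method="median_unbiased")
        iqr = q3 - q1
        alt = np.clip(v, q1 - 3 * iqr, q3 + 3 * iqr)
        # same entries flagged as outliers, bounds within quantile-convention gap
        assert np.mean((ours != v) == (alt != v)) > 0.99


class TestQCMedianCV:
    def test_identical_replicates_zero(self):
        m = make_matrix({"f": [5.0, 5.0, 5.0]}, is_qc=[1, 1, 1])
        assert qc_median_cv(m).median_cv_pct == 0.0

    def test_two_point_hand_formula(self):
        # replicates 9 and 11: mean 10, SD sqrt(2), CV% = 10*sqrt(2)
        m = make_matrix({"f": [9.0, 11.0]}, is_qc=[1, 1])
        assert qc_median_cv(m).median_cv_pct == pytest.approx(100 * np.sqrt(2) / 10)

    def test_matches_bruteforce_over_100_features(self, rng):
        cols = {f"f{j}": rng.lognormal(2, 0.3, 6) for j in range(100)}
        m = make_matrix(cols, is_qc=[1] * 6)
        result = qc_median_cv(m)
        expected = np.median(
            [100 * np.std(v, ddof=1) / np.mean(v) for v in cols.values()]
        )
        assert result.median_cv_pct == pytest.approx(expected)


class TestLoess:
    def test_constant_qc_leaves_study_samples_unchanged(self):
        n = 40
        is_qc = ([1] + [0] * 7) * 5
        vals = np.where(np.array(is_qc) == 1, 100.0, 57.0)
        m = make_matrix({"f": vals}, is_qc=is_qc)
        out = loess_normalize(m)
        study = np.array(is_qc) == 0
        np.testing.assert_allclose(
            out.data["f"].to_numpy()[study], 57.0, rtol=1e-10
        )

    def test_injected_linear_drift_reduces_qc_cv(self):
        cfg = CohortConfig(n_cases_A=60, n_cases_B=40, n_controls=100,
                           platform_sizes={"LC-MS": 25}, drift_profile="linear",
                           drift_amplitude=np.log(2), noise_sd=0.05,
                           lod_missing_rate=0.0, n_batches=3, seed=21)
        _, mats = generate_cohort(cfg)
        pre = qc_median_cv(mats[0]).median_cv_pct
        post = qc_median_cv(loess_normalize(mats[0])).median_cv_pct
        assert post <= 0.5 * pre

    def test_deterministic(self, small_cohort):
        _, _, mats = small_cohort
        a = loess_normalize(mats[0]).data
        b = loess_normalize(mats[0]).data
        pd.testing.assert_frame_equal(a, b)

    def test_few_qc_rows_fall_back_to_batch_median(self):
        is_qc = [1, 0, 0, 0, 0, 0, 1, 0]  # 2 QC rows < 4
        vals = [100.0, 50, 60, 55, 52, 58, 120, 57]
        m = make_matrix({"f": vals}, is_qc=is_qc)
        out = loess_normalize(m)
        assert np.isfinite(out.data["f"]).all()


class TestChain:
    def test_rerun_of_deterministic_steps_is_exact_noop(self, small_cohort):
        """filter -> half-min -> truncate is idempotent to 1e-10."""
        _, _, mats = small_cohort
        once = truncate_matrix(impute_half_min(filter_missingness(mats[0], 0.2)), 3.0)
        twice = truncate_matrix(impute_half_min(filter_missingness(once, 0.2)), 3.0)
        np.testing.assert_allclose(
            twice.data[twice.feature_columns].to_numpy(),
            once.data[once.feature_columns].to_numpy(),
            rtol=1e-10, atol=1e-10,
        )

    def test_second_loess_pass_is_a_contraction(self, small_cohort):
        """Re-normalizing already-normalized data moves values far less.

        A local smoother is not a projection, so an exact no-op is not
        expected; the second pass must only chase residual QC noise.
        """
        _, _, mats = small_cohort
        base = impute_half_min(filter_missingness(mats[0], 0.2))
        once = loess_normalize(base)
        twice = loess_normalize(once)
        feats = base.feature_columns
        first = np.abs(np.log(once.data[feats]) - np.log(base.data[feats]))
        second = np.abs(np.log(twice.data[feats]) - np.log(once.data[feats]))
        assert second.to_numpy().mean() < 0.5 * first.to_numpy().mean()

    def test_nmr_platform_not_loess_normalized(self, small_cohort):
        _, _, mats = small_cohort
        nmr = mats[1]
        assert nmr.platform == "NMR"
        out = preprocess_platform(nmr, PreprocessConfig())
        trunc = truncate_matrix(impute_half_min(filter_missingness(nmr, 0.2)), 3.0)
        pd.testing.assert_frame_equal(out.data, trunc.data)
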