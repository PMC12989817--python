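"""Missingness filter, down-shifted-normal imputation, normalizations."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_design, make_logmatrix
from turbomap import (ImputeParams, filter_by_missingness, impute,
                      normalize_to_bait, quantile_normalize)
from turbomap.errors import ConfigError, DataError

NA = np.nan


@pytest.fixture()
def groups_design():
    rows = []
    for g in ("control", "N_term"):
        rows += [(f"AP_{g}_{r}", g, "AP", r) for r in (1, 2, 3)]
    return make_design(rows)


COLS = ["AP_control_1", "AP_control_2", "AP_control_3",
        "AP_N_term_1", "AP_N_term_2", "AP_N_term_3"]


class TestMissingnessFilter:
    def test_kept_if_half_valid_in_one_cohort(self, groups_design):
        m = make_logmatrix([[NA, NA, NA, 20, 21, NA]], COLS)
        out = filter_by_missingness(m, groups_design, 0.5)
        assert len(out.values) == 1  # 2/3 in N_term suffices

    def test_removed_if_below_threshold_everywhere(self, groups_design):
        m = make_logmatrix([[20, NA, NA, 20, NA, NA]], COLS)
        out = filter_by_missingness(m, groups_design, 0.5)
        assert len(out.values) == 0  # 1/3 in every cohort

    def test_threshold_one_needs_fully_observed_cohort(self, groups_design):
        m = make_logmatrix([[20, 21, 22, NA, NA, NA],
                            [20, 21, NA, NA, NA, NA]], COLS)
        out = filter_by_missingness(m, groups_design, 1.0)
        assert list(out.values.index) == ["P0"]

    def test_invalid_threshold_rejected(self, groups_design):
        m = make_logmatrix([[20, 21, 22, 20, 21, 22]], COLS)
        with pytest.raises(ConfigError):
            filter_by_missingness(m, groups_design, 0.0)


class TestImpute:
    def test_complete_matrix_identity(self):
        m = make_logmatrix([[20, 21], [22, 23]], ["a", "b"])
        out = impute(m, ImputeParams(seed=1))
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_deterministic_and_observed_bit_identical(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(25, 2, (400, 4))
        vals[rng.random(vals.shape) < 0.3] = NA
        m = make_logmatrix(vals, list("abcd"))
        o1 = impute(m, ImputeParams(seed=42))
        o2 = impute(m, ImputeParams(seed=42))
        pd.testing.assert_frame_equal(o1.values, o2.values)
        obs = ~np.isnan(vals)
        assert (o1.values.to_numpy()[obs] == vals[obs]).all()
        assert not o1.values.isna().any().any()

    def test_imputed_distribution_matches_downshifted_normal(self):
        """Law-of-large-numbers oracle: 10,000+ imputed cells in a column
        with observed mean 25, sd 2 land at mean 25-1.8*2, sd 0.3*2."""
        rng = np.random.default_rng(7)
        n_obs, n_miss = 200_000, 12_000
        obs = rng.normal(25.0, 2.0, n_obs)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 25.0  # exact moments
        col = np.concatenate([obs, np.full(n_miss, NA)])
        m = make_logmatrix(col[:, None], ["s1"])
        out = impute(m, ImputeParams(seed=3))
        imputed = out.values.to_numpy()[n_obs:, 0]
        assert abs(imputed.mean() - (25 - 1.8 * 2)) < 0.07
        assert abs(imputed.std(ddof=1) - 0.3 * 2) < 0.02

    def test_column_with_single_observation_rejected(self):
        m = make_logmatrix([[20, 20], [NA, 21], [NA, 22]], ["a", "b"])
        with pytest.raises(DataError):
            impute(m, ImputeParams(seed=0))


class TestBaitNormalization:
    def test_hand_computed_example(self):
        """bait (20, 22), protein (10, 12) -> (11, 11) with mean bait 21."""
        design = make_design([("s1", "N_term", "AP", 1),
                              ("s2", "N_term", "AP", 2)])
        m = make_logmatrix([[20, 22], [10, 12]], ["s1", "s2"],
                           index=["BAIT", "P1"])
        out = normalize_to_bait(m, design, "BAIT")
        assert out.values.loc["P1"].tolist() == [11.0, 11.0]
        assert out.values.loc["BAIT"].tolist() == [21.0, 21.0]

    def test_equal_bait_is_identity(self):
        design = make_design([("s1", "N_term", "AP", 1),
                              ("s2", "N_term", "AP", 2)])
        m = make_logmatrix([[21, 21], [10, 12]], ["s1", "s2"],
                           index=["BAIT", "P1"])
        out = normalize_to_bait(m, design, "BAIT")
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_bait_row_constant_and_differences_preserved(self):
        rng = np.random.default_rng(0)
        design = make_design(
            [(f"s{j}", "N_term", "AP", j) for j in range(1, 7)])
        vals = rng.normal(25, 2, (50, 6))
        m = make_logmatrix(vals, [f"s{j}" for j in range(1, 7)],
                           index=["BAIT"] + [f"P{i}" for i in range(49)])
        out = normalize_to_bait(m, design, "BAIT")
        assert np.allclose(out.values.loc["BAIT"].std(ddof=0), 0.0)
        # within-sample pairwise differences are untouched
        before = vals[1:, :] - vals[:1, :]
        after = out.values.to_numpy()[1:, :] - out.values.to_numpy()[:1, :]
        np.testing.assert_array_equal(before, after)

    def test_control_samples_untouched(self):
        design = make_design([("c1", "control", "AP", 1),
                              ("s1", "N_term", "AP", 1),
                              ("s2", "N_term", "AP", 2)])
        m = make_logmatrix([[18, 20, 22], [9, 10, 12]], ["c1", "s1", "s2"],
                           index=["BAIT", "P1"])
        out = normalize_to_bait(m, design, "BAIT")
        assert out.values["c1"].tolist() == [18.0, 9.0]

    def test_missing_bait_names_sample(self):
        design = make_design([("s1", "N_term", "AP", 1),
                              ("s2", "N_term", "AP", 2)])
        m = make_logmatrix([[20, NA], [10, 12]], ["s1", "s2"],
                           index=["BAIT", "P1"])
        with pytest.raises(DataError, match="s2"):
            normalize_to_bait(m, design, "BAIT")


class TestQuantileNormalize:
    def test_hand_computed_example(self):
        m = make_logmatrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
                           ["a", "b"])
        out = quantile_normalize(m)
        assert out.values["a"].tolist() == [2.5, 3.5, 4.5]
        assert out.values["b"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_are_identity(self):
        m = make_logmatrix(np.array([[5.0, 5.0], [1.0, 1.0], [3.0, 3.0]]),
                           ["a", "b"])
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_idempotent_and_sorted_columns_equal(self):
        rng = np.random.default_rng(2)
        m = make_logmatrix(rng.normal(25, 2, (200, 5)), list("abcde"))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        ref = np.sort(once.values.to_numpy()[:, 0])
        for j in range(5):
            np.testing.assert_allclose(
                np.sort(once.values.to_numpy()[:, j]), ref, rtol=0, atol=0)

    def test_ties_share_rank_range_mean(self):
        m = make_logmatrix(np.array([[1.0, 10.0], [1.0, 20.0], [4.0, 30.0]]),
                           ["a", "b"])
        out = quantile_normalize(m)
        ref = np.array([11.0 / 2, 21.0 / 2, 34.0 / 2])
        np.testing.assert_allclose(out.values["b"], ref)
        # the tied pair in column a shares the mean of ref ranks 1-2
        np.testing.assert_allclose(out.values["a"],
                                   [(ref[0] + ref[1]) / 2,
                                    (ref[0] + ref[1]) / 2, ref[2]])

    def test_missing_values_rejected(self):
        m = make_logmatrix([[1.0, NA]], ["a", "b"])
        with pytest.raises(DataError):
            quantile_normalize(m)
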