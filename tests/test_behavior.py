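"""Behavioral decomposition: error geometry, filters, bias subtraction,
summaries, exclusions, standardization and cross-measure statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from swmkit import behavior, synthdata
from swmkit.behavior import FilterRules

from conftest import make_trials


class TestDecompose:
    def test_direct_formulas(self):
        t = make_trials([60.0], [65.0], target_amp=6.0, response_amp=[5.4])
        e = behavior.decompose_errors(t).iloc[0]
        assert e["angular_error"] == pytest.approx(5.0)
        assert e["amplitude_error"] == pytest.approx(-0.6)
        assert e["d"] == pytest.approx(15.0)
        assert e["toward_error"] == pytest.approx(-5.0)

    def test_wraparound(self):
        t = make_trials([350.0], [5.0])
        e = behavior.decompose_errors(t).iloc[0]
        assert e["angular_error"] == pytest.approx(15.0)

    def test_nearest_diagonal_distance(self):
        # 100 deg sits 35 deg clockwise of the 135 deg diagonal
        t = make_trials([100.0], [100.0])
        assert behavior.decompose_errors(t).iloc[0]["d"] == pytest.approx(-35.0)

    def test_zero_target_amplitude_rejected(self):
        t = make_trials([60.0], [65.0], target_amp=0.0)
        with pytest.raises(ValueError):
            behavior.decompose_errors(t)

    def test_pixel_conversion_roundtrip(self):
        px = 40.0
        df = pd.DataFrame(
            {
                "target_x_px": [px * 6 * np.cos(np.radians(60))],
                "target_y_px": [px * 6 * np.sin(np.radians(60))],
                "response_x_px": [px * 5.4 * np.cos(np.radians(65))],
                "response_y_px": [px * 5.4 * np.sin(np.radians(65))],
            }
        )
        out = behavior.trials_from_pixels(df, px_per_dva=px)
        assert out["target_angle_deg"].iloc[0] == pytest.approx(60.0)
        assert out["target_amp_dva"].iloc[0] == pytest.approx(6.0)
        assert out["response_angle_deg"].iloc[0] == pytest.approx(65.0)
        assert out["response_amp_dva"].iloc[0] == pytest.approx(5.4)

    @given(
        target=st.floats(0.0, 359.999),
        response=st.floats(-720.0, 720.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_wrap_and_distance_ranges(self, target, response):
        t = make_trials([target], [response])
        e = behavior.decompose_errors(t).iloc[0]
        assert -180.0 < e["angular_error"] <= 180.0
        assert -45.0 <= e["d"] <= 45.0
        # sign convention: positive toward_error iff rotated toward diagonal
        if e["d"] != 0 and e["angular_error"] != 0:
            rotated_toward = np.sign(e["angular_error"]) == -np.sign(e["d"])
            assert (e["toward_error"] > 0) == rotated_toward


class TestFilters:
    def test_angle_window(self):
        t = make_trials([60.0, 60.0], [110.0, 70.0])
        f = behavior.apply_trial_filters(behavior.decompose_errors(t))
        assert f["window_angle"].tolist() == [True, False]

    def test_amplitude_window(self):
        t = make_trials([60.0] * 2, [60.0] * 2, target_amp=6.0,
                        response_amp=[2.4, 6.0])  # 0.4x target
        f = behavior.apply_trial_filters(behavior.decompose_errors(t))
        assert f["window_amp"].tolist() == [True, False]

    def test_iqr_rule_matches_brute_force_quartiles(self):
        # angular errors {1,2,3,4,44}: Q1=2, Q3=4, fences [-1, 7] -> 44 flagged
        angles = np.array([1.0, 2.0, 3.0, 4.0, 44.0])
        t = make_trials(np.full(5, 60.0), 60.0 + angles)
        f = behavior.apply_trial_filters(behavior.decompose_errors(t))
        vals = sorted(angles)
        q1 = np.percentile(vals, 25, method="linear")
        q3 = np.percentile(vals, 75, method="linear")
        assert (q1, q3) == (2.0, 4.0)
        expected = [(v < q1 - 1.5 * (q3 - q1)) or (v > q3 + 1.5 * (q3 - q1))
                    for v in angles]
        assert f["iqr_angle"].tolist() == expected
        assert f["excluded"].tolist() == expected

    def test_iqr_computed_after_window_stage(self):
        # the 50 deg trial is window-excluded first, so IQR fences come from
        # the survivors and still catch the 44 deg trial
        angles = np.array([1.0, 2.0, 3.0, 4.0, 44.0, 50.0])
        t = make_trials(np.full(6, 60.0), 60.0 + angles)
        f = behavior.apply_trial_filters(behavior.decompose_errors(t))
        assert f["window_angle"].tolist()[-1]
        assert f["iqr_angle"].tolist()[4]

    def test_few_trials_skip_iqr_stage(self, caplog):
        t = make_trials([60.0] * 3, [61.0, 62.0, 63.0])
        f = behavior.apply_trial_filters(behavior.decompose_errors(t))
        assert not f["iqr_angle"].any()

    def test_filter_idempotence(self, small_dataset):
        trials, _ = small_dataset
        f1 = behavior.apply_trial_filters(behavior.decompose_errors(trials))
        survivors = f1[~f1["excluded"]].drop(
            columns=["window_angle", "window_amp", "iqr_angle", "iqr_amp",
                     "excluded"]
        )
        f2 = behavior.apply_trial_filters(survivors)
        assert not f2["window_angle"].any()
        assert not f2["window_amp"].any()

    def test_planted_outliers_are_caught(self, default_dataset):
        _, (trials, _) = default_dataset
        f = behavior.apply_trial_filters(behavior.decompose_errors(trials))
        planted = trials["planted_outlier"].to_numpy()
        assert f.loc[planted, "excluded"].mean() > 0.99


class TestBiasAndPureErrors:
    def test_uniform_shift_toward_diagonal(self):
        # zero-noise trials all shifted +6 deg toward the diagonal at |d|=15
        targets = np.array([60.0, 30.0, 120.0, 150.0])  # d = +15,-15,-15,+15
        d = behavior.signed_diagonal_distance(targets)
        resp = targets - np.sign(d) * 6.0
        t = make_trials(targets, resp)
        f = behavior.apply_trial_filters(behavior.decompose_errors(t))
        profiles, amp_bias = behavior.estimate_bias_profiles(f)
        assert profiles["abs_d"].tolist() == [15.0]
        assert profiles["bias_deg"].iloc[0] == pytest.approx(6.0)
        assert amp_bias["amplitude_bias"].iloc[0] == pytest.approx(0.0)

    def test_on_target_responses_give_zero_bias(self):
        targets = np.array([60.0, 30.0, 120.0, 150.0, 200.0])
        t = make_trials(targets, targets)
        f = behavior.apply_trial_filters(behavior.decompose_errors(t))
        profiles, amp_bias = behavior.estimate_bias_profiles(f)
        assert np.allclose(profiles["bias_deg"], 0.0)
        assert amp_bias["amplitude_bias"].iloc[0] == 0.0

    def test_generator_bias_profile_is_w_times_d(self):
        """Zero noise, w=0.3: estimated bias equals 0.3|d| in every bin."""
        cfg = synthdata.GeneratorConfig(
            n_studies=1, participants_per_study=(3,), target_amplitude=(6.0,),
            trials_per_participant=48, sigma_range=(1e-12, 1e-12),
            w_range=(0.3, 0.3), outlier_prob=0.0, seed=2,
        )
        trials, _ = synthdata.generate_dataset(cfg)
        f = behavior.apply_trial_filters(behavior.decompose_errors(trials))
        profiles, _ = behavior.estimate_bias_profiles(f)
        np.testing.assert_allclose(
            profiles["bias_deg"], 0.3 * profiles["abs_d"], atol=1e-6
        )

    def test_exact_cancellation(self):
        targets = np.full(4, 60.0)           # d = +15
        resp = np.array([54.0, 54.0, 54.0, 54.0])  # angular_error = -6
        t = make_trials(targets, resp)
        f = behavior.apply_trial_filters(behavior.decompose_errors(t))
        profiles, amp_bias = behavior.estimate_bias_profiles(f)
        assert profiles["bias_deg"].iloc[0] == pytest.approx(6.0)
        pure = behavior.compute_pure_errors(f, profiles, amp_bias)
        np.testing.assert_allclose(pure["pure_angular_error"], 0.0, atol=1e-12)

    def test_zero_bias_profile_is_identity(self):
        targets = np.array([60.0, 30.0, 120.0, 150.0])
        t = make_trials(targets, targets + np.array([1.0, -1.0, 1.0, -1.0]))
        f = behavior.apply_trial_filters(behavior.decompose_errors(t))
        profiles, amp_bias = behavior.estimate_bias_profiles(f)
        profiles = profiles.assign(bias_deg=0.0)
        amp_bias = amp_bias.assign(amplitude_bias=0.0)
        pure = behavior.compute_pure_errors(f, profiles, amp_bias)
        np.testing.assert_allclose(
            pure["pure_angular_error"], pure["angular_error"], atol=1e-12
        )

    def test_within_bin_mean_of_pure_errors_is_zero(self, default_analysis):
        result, _ = default_analysis
        good = result.errors[~result.errors["excluded"]]
        binned = good[good["abs_d"] > 0]
        means = binned.groupby(["participant_id", "abs_d"])[
            "pure_angular_error"
        ].mean()
        # toward-frame residuals average to zero per bin; in the angular
        # frame the sign flip within a bin preserves the zero mean only per
        # signed-d cell, so check the toward-frame residual directly
        resid = -np.sign(binned["d"]) * binned["pure_angular_error"]
        means_toward = resid.groupby(
            [binned["participant_id"], binned["abs_d"]]
        ).mean()
        assert np.abs(means_toward).max() < 1e-10
        assert means.notna().all()


class TestSummaries:
    def test_zero_pure_errors_summarize_to_zero(self):
        targets = np.array([60.0, 30.0, 120.0, 150.0])
        t = make_trials(targets, targets)
        f = behavior.apply_trial_filters(behavior.decompose_errors(t))
        profiles, amp_bias = behavior.estimate_bias_profiles(f)
        pure = behavior.compute_pure_errors(f, profiles, amp_bias)
        s = behavior.summarize_participants(pure, profiles, amp_bias)
        assert s["pure_angular_error"].iloc[0] == 0.0

    def test_rmsd_closed_form(self):
        # bias profile {3, 4} over two bins -> sqrt((9+16)/2) = 3.5355
        targets = np.array([60.0, 30.0, 65.0, 25.0])  # |d| = 15, 20
        d = behavior.signed_diagonal_distance(targets)
        resp = targets - np.sign(d) * np.array([3.0, 3.0, 4.0, 4.0])
        t = make_trials(targets, resp)
        f = behavior.apply_trial_filters(behavior.decompose_errors(t))
        profiles, amp_bias = behavior.estimate_bias_profiles(f)
        pure = behavior.compute_pure_errors(f, profiles, amp_bias)
        s = behavior.summarize_participants(pure, profiles, amp_bias)
        assert s["angular_bias_rmsd"].iloc[0] == pytest.approx(3.5355, abs=1e-4)

    def test_sigma_grid_recovery(self):
        """Participants on a sigma grid rank-recover through the summary."""
        cfg = synthdata.GeneratorConfig(
            n_studies=1, participants_per_study=(36,), target_amplitude=(6.0,),
            trials_per_participant=60, sigma_range=(1.0, 6.0),
            w_range=(0.0, 0.0), outlier_prob=0.0, seed=13,
        )
        trials, truths = synthdata.generate_dataset(cfg)
        res = behavior.analyze(trials, with_stats=False)
        m = res.summaries.merge(
            synthdata.truths_to_frame(truths), on=["study_id", "participant_id"]
        )
        rho = stats.spearmanr(m["sigma"], m["pure_angular_error"]).statistic
        assert rho >= 0.9


class TestExclusionAndStandardization:
    def _summaries(self, rmsd_values):
        n = len(rmsd_values)
        return pd.DataFrame(
            {
                "study_id": "S1",
                "participant_id": [f"P{i}" for i in range(n)],
                "pure_angular_error": np.linspace(2, 4, n),
                "angular_bias_rmsd": rmsd_values,
                "amplitude_bias": 0.0,
                "n_trials_surviving": 50,
                "pct_trials_excluded": 0.0,
                "excluded": False,
            }
        )

    def test_single_extreme_participant_flagged(self):
        rng = np.random.default_rng(0)
        s = self._summaries(np.append(2.0 + 0.2 * rng.standard_normal(20), 40.0))
        out = behavior.exclude_outlier_participants(s)
        assert out["excluded"].sum() == 1
        assert out.loc[out.index[-1], "excluded"]

    def test_equal_values_none_flagged(self):
        out = behavior.exclude_outlier_participants(self._summaries([2.0] * 10))
        assert not out["excluded"].any()

    def test_infinite_k_flags_nothing(self):
        s = self._summaries(np.append(np.full(10, 2.0), 1000.0))
        out = behavior.exclude_outlier_participants(s, k=np.inf)
        assert not out["excluded"].any()

    def test_zscores_match_sample_sd(self):
        s = self._summaries([1.0, 2.0, 3.0])
        out = behavior.standardize_within_study(s)
        np.testing.assert_allclose(out["z_angular_bias"], [-1.0, 0.0, 1.0])

    def test_constant_measure_is_error(self):
        with pytest.raises(ValueError):
            behavior.standardize_within_study(self._summaries([2.0, 2.0, 2.0]))

    def test_standardized_moments(self, default_analysis):
        result, _ = default_analysis
        good = result.summaries[~result.summaries["excluded"]]
        for col in ("z_pure_angular_error", "z_angular_bias"):
            g = good.groupby("study_id")[col]
            assert np.abs(g.mean()).max() < 1e-12
            assert np.abs(g.std(ddof=1) - 1.0).max() < 1e-12


class TestCorrelateAndCompare:
    def test_perfect_linear_relation(self):
        n = 12
        s = pd.DataFrame(
            {
                "study_id": ["S1"] * 6 + ["S2"] * 6,
                "participant_id": [f"P{i}" for i in range(n)],
                "pure_angular_error": np.tile(np.arange(6.0), 2) + 2,
                "angular_bias_rmsd": 2 * (np.tile(np.arange(6.0), 2) + 1),
                "amplitude_bias": 0.0,
                "n_trials_surviving": 50,
                "pct_trials_excluded": 0.0,
                "excluded": False,
            }
        )
        out = behavior.standardize_within_study(s)
        stats_out = behavior.correlate_and_compare(out)
        assert stats_out["pearson_r"] == pytest.approx(1.0)

    def test_default_design_anova_df(self, default_analysis):
        result, _ = default_analysis
        # 153 participants in 6 studies, none excluded in this realization
        anova = result.stats["anova"]["pure_angular_error"]
        n_kept = int((~result.summaries["excluded"]).sum())
        assert anova["df1"] == 5
        assert anova["df2"] == n_kept - 6

    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(0.8, 1, 25)
        res = behavior.one_way_anova(
            np.concatenate([a, b]),
            np.array(["A"] * 20 + ["B"] * 25),
        )
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res["F"] == pytest.approx(t**2, rel=1e-10)
        assert res["p"] == pytest.approx(p, rel=1e-10)
        f_sp = stats.f_oneway(a, b)
        assert res["F"] == pytest.approx(f_sp.statistic, rel=1e-10)
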