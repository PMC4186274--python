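"""Synthetic-observer generator: determinism, calibration and structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mpdepth import (
    SimulationConfig,
    StimulusCondition,
    aggregate_trials,
    build_stimulus_grid,
    depth_to_disparity,
    empirical_depth,
    fit_cumulative_normal,
    head_speed_to_pursuit_rate,
    simulate_depth_constancy_control,
    simulate_head_translation_session,
    simulate_trials,
)
from mpdepth.observer import lognormal_noise


class TestStimulusGrid:
    def test_117_trial_types_per_condition(self, default_grid):
        assert (default_grid.groupby("condition_id").size() == 117).all()
        assert default_grid["condition_id"].nunique() == 6

    def test_ratios_within_published_bounds(self, default_grid):
        ratio = default_grid["dtheta_deg_s"] / default_grid["dalpha_deg_s"]
        assert ratio.between(0.042 - 1e-9, 0.25 + 1e-9).all()

    def test_stationary_rates_within_published_bounds(self, default_grid):
        stat = default_grid[default_grid["head_state"] == "stationary"]
        assert stat["dalpha_deg_s"].between(1.1, 11.57).all()
        assert stat["dtheta_deg_s"].between(0.14, 1.65 + 1e-9).all()

    def test_replicated_pursuit_speed_in_both_36cm_conditions(self, default_grid):
        stat = default_grid[default_grid["f_cm"] == 36.0]
        stat = stat[stat["head_state"] == "stationary"]
        by_cond = stat.groupby("condition_id")["dalpha_deg_s"].unique()
        assert all(4.95 in speeds for speeds in by_cond)

    def test_disparity_levels_are_pixel_multiples(self, default_grid):
        # level 9 at 36 cm subtends 9 pixels * 2.33 arcmin = 20.97 arcmin
        at36 = default_grid[default_grid["f_cm"] == 36.0]
        top = at36[at36["disparity_pixels"] == 9]["disparity_arcmin"].unique()
        assert top == pytest.approx(20.9703, abs=1e-3)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            SimulationConfig(stationary_grid={"bad": (36.0, [(1.5, 4.95)])})

    def test_invalid_pursuit_gain_rejected(self):
        with pytest.raises(ValueError, match="pursuit_gain"):
            SimulationConfig(pursuit_gain=0.0)


class TestSimulateTrials:
    def test_determinism(self, small_config, default_grid):
        a = simulate_trials(default_grid, small_config, seed=11)
        b = simulate_trials(default_grid, small_config, seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_trials(default_grid, small_config, seed=12)
        assert not a["response_stereo_deeper"].equals(c["response_stereo_deeper"])

    def test_noiseless_responses_form_exact_step(self, default_grid):
        config = dataclasses.replace(
            SimulationConfig(), noise_cv=0.0, n_observers=1, n_blocks=1
        )
        trials = simulate_trials(default_grid, config, seed=0)
        agg = aggregate_trials(trials)
        # responses are a deterministic threshold on disparity depth
        for (_, f, dtheta, dalpha, _), sub in agg.groupby(
            ["condition_id", "f_cm", "dtheta_deg_s", "dalpha_deg_s", "head_state"]
        ):
            d_mp = empirical_depth(StimulusCondition(f=f, dtheta=dtheta, dalpha=dalpha))
            threshold = depth_to_disparity(d_mp, f, config.i)
            expect = (sub["disparity_arcmin"] > threshold).astype(float)
            assert (sub["proportion"].to_numpy() == expect.to_numpy()).all()

    def test_internal_depth_mean_converges_to_empirical(self):
        # mean of the lognormal-noised internal depth matches the model
        rng = np.random.default_rng(5)
        cond = StimulusCondition(f=36, dtheta=0.5, dalpha=4.95)
        d = empirical_depth(cond) * lognormal_noise(rng, 0.15, 10_000)
        assert abs(d.mean() / empirical_depth(cond) - 1) < 0.01

    def test_fitted_pse_increases_with_dtheta(self):
        # monotonicity of perceived depth in retinal speed, via fitted PSEs
        grid_spec = {"m": (36.0, [(r, 4.95) for r in (0.05, 0.1, 0.2)])}
        config = dataclasses.replace(
            SimulationConfig(), stationary_grid=grid_spec, translating_grid={},
            n_observers=4, n_blocks=20,
        )
        trials = simulate_trials(build_stimulus_grid(config), config, seed=21)
        agg = aggregate_trials(trials)
        pses = []
        for dtheta, sub in agg.groupby("dtheta_deg_s"):
            pses.append((dtheta, fit_cumulative_normal(sub).pse))
        pses.sort()
        values = [p for _, p in pses]
        assert values == sorted(values)


class TestHeadTranslation:
    def test_nominal_total_eye_speed(self, default_grid):
        trans = default_grid[default_grid["head_state"] == "translating"]
        at36 = trans[trans["f_cm"] == 36.0]["dalpha_deg_s"].unique()
        assert at36 == pytest.approx(head_speed_to_pursuit_rate(11.0, 36))
        assert at36 == pytest.approx(17.5, abs=0.05)

    def test_head_speeds_vary_but_stay_positive(self, small_config, default_grid):
        trials = simulate_head_translation_session(default_grid, small_config, seed=2)
        assert trials["head_speed_cm_s"].gt(0).all()
        assert trials["head_speed_cm_s"].std() > 0

    def test_pursuit_scaled_equivalence_with_stationary(self):
        """A translating session matches a stationary session run at the
        pursuit fraction of the total eye speed, at the same M/PR."""
        gain = 0.4
        ratios = [0.08, 0.15, 0.25]
        total = head_speed_to_pursuit_rate(11.0, 36)  # 17.5 deg/s
        config_t = dataclasses.replace(
            SimulationConfig(),
            pursuit_gain=gain,
            stationary_grid={},
            translating_grid={"T": (36.0, 11.0, 0.0, ratios)},  # fixed head speed
            n_observers=6, n_blocks=30,
        )
        trials_t = simulate_head_translation_session(
            build_stimulus_grid(config_t), config_t, seed=31)
        config_s = dataclasses.replace(
            SimulationConfig(),
            stationary_grid={"S": (36.0, [(r, gain * total) for r in ratios])},
            translating_grid={},
            n_observers=6, n_blocks=30,
        )
        trials_s = simulate_trials(build_stimulus_grid(config_s), config_s, seed=32)

        for trials, tag in ((trials_t, "t"), (trials_s, "s")):
            agg = aggregate_trials(trials)
            fits = {}
            for key, sub in agg.groupby("dtheta_deg_s"):
                ratio = key / sub["dalpha_deg_s"].iloc[0]
                fits[round(ratio, 3)] = fit_cumulative_normal(sub).pse
            if tag == "t":
                pse_t = fits
            else:
                pse_s = fits
        for ratio in (0.08, 0.15, 0.25):
            assert pse_t[ratio] == pytest.approx(pse_s[ratio], rel=0.03)

    def test_gain_scales_effective_pursuit(self):
        assert 0.4 * 17.5 == pytest.approx(7.0)


class TestDepthConstancyControl:
    def test_perfect_constancy_noiseless_pse(self):
        config = dataclasses.replace(SimulationConfig(), noise_cv=0.0)
        trials = simulate_depth_constancy_control(config, seed=0, n_observers=1,
                                                  n_blocks=1)
        from mpdepth import analyze_constancy

        summary = analyze_constancy(trials, i=config.i)
        fix36 = summary[summary["condition_id"] == "C_fix36"].iloc[0]
        # variable at 72 cm matches 23.3 arcmin at 36 cm at the quarter
        # disparity: 23.3 * (36/72)**2 = 5.825 arcmin
        assert fix36["expected_pse_arcmin"] == pytest.approx(5.825)
        assert fix36["pse_arcmin"] == pytest.approx(5.825, abs=0.4)

    def test_disparity_matcher_produces_fourfold_mismatch(self):
        # probe a range wide enough to contain the raw-disparity match;
        # within the study's 1.2-11.7' range such an observer saturates
        wide = {"C_fix36": (36.0, 23.3, 72.0, (10.0, 36.0))}
        trials = simulate_depth_constancy_control(
            observer_model="disparity_matcher", conditions=wide, seed=4)
        from mpdepth import analyze_constancy

        summary = analyze_constancy(trials, i=6.5)
        fix36 = summary[summary["condition_id"] == "C_fix36"].iloc[0]
        # matching raw disparity puts the PSE at the fixed 23.3 arcmin, a
        # 4-fold depth mismatch after distance-square scaling
        assert fix36["pse_arcmin"] == pytest.approx(23.3, rel=0.05)
        assert fix36["normalized_match"] == pytest.approx(4.0, rel=0.06)

    def test_distance_misestimate_shifts_pse_by_squared_factor(self):
        config = dataclasses.replace(SimulationConfig(), noise_cv=0.05)
        trials = simulate_depth_constancy_control(
            config, observer_model="distance_misestimate", misestimate=0.10,
            seed=5)
        from mpdepth import analyze_constancy

        summary = analyze_constancy(trials, i=config.i)
        fix36 = summary[summary["condition_id"] == "C_fix36"].iloc[0]
        # variable at 72 cm under-estimated by 10%: perceived depth smaller
        # by 0.9**2, so a larger disparity is needed: PSE / expected = 1/0.81
        assert fix36["pse_arcmin"] / fix36["expected_pse_arcmin"] == pytest.approx(
            1 / 0.81, rel=0.05
        )

    def test_unknown_observer_model_rejected(self):
        with pytest.raises(ValueError, match="observer_model"):
            simulate_depth_constancy_control(observer_model="psychic")

    def test_near_perfect_constancy_at_study_scale(self):
        """Normalized depth matches stay within 2% of unity (averaged over
        seeded replicate sessions at the 9-observer, 2-block scale)."""
        from mpdepth import analyze_constancy

        matches = []
        for seed in range(5):
            trials = simulate_depth_constancy_control(seed=seed)
            summary = analyze_constancy(trials, i=6.5)
            matches.append(summary["normalized_match"].to_numpy())
        mean_match = np.mean(matches, axis=0)
        assert np.all(mean_match > 0.98) and np.all(mean_match < 1.02)


def test_identical_seed_gives_identical_csv(tmp_path, small_config, default_grid):
    from mpdepth import write_trials

    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    for p in (p1, p2):
        trials = simulate_trials(default_grid, small_config, seed=9)
        write_trials(trials, p, provenance={"seed": 9})
    assert p1.read_bytes() == p2.read_bytes()
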