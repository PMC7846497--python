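import dataclasses

import numpy as np
import pytest

from lvattention.interactions import Role, adaptive_eps, classify_system, detect_intensification
from lvattention.lv_dynamics import CoefficientSet
from lvattention.pipeline import RunConfig, analyze_series
from lvattention.share_model import to_shares
from lvattention.synthetic_data import (
    Regime,
    SyntheticScenario,
    generate,
    pandemic_preset,
    scenario_from_dict,
    scenario_to_dict,
    trendsify,
)
from lvattention.utility_fit import FourierUtility, fit_utilities

from conftest import random_fourier_system


def single_regime_scenario(rng, order=2, **overrides):
    times = np.arange(52, dtype=float)
    tau = float(times[-1])
    topics = ("w", "x", "y", "z")
    utilities = tuple(
        FourierUtility(
            a0=rng.normal(-1.0, 0.4),
            a=rng.normal(0.0, 0.3, order),
            b=rng.normal(0.0, 0.3, order),
            tau=tau,
        )
        for _ in topics
    )
    defaults = dict(
        topics=topics,
        regimes=(Regime(0.0, utilities),),
        span=52,
        noise_sd=0.0,
        round_to_int=False,
        seed=9,
    )
    defaults.update(overrides)
    return SyntheticScenario(**defaults)


class TestGenerate:
    def test_same_seed_identical_output(self, rng):
        scenario = single_regime_scenario(rng, noise_sd=2.0, round_to_int=True)
        series1, _ = generate(scenario)
        series2, _ = generate(scenario)
        assert series1 == series2

    def test_different_seed_differs(self, rng):
        scenario = single_regime_scenario(rng, noise_sd=2.0)
        series1, _ = generate(scenario)
        series2, _ = generate(dataclasses.replace(scenario, seed=10))
        assert series1 != series2

    def test_max_cell_is_100_pre_noise(self, rng):
        series, _ = generate(single_regime_scenario(rng))
        assert np.isclose(max(s.values.max() for s in series), 100.0)

    def test_output_satisfies_series_invariants(self, rng):
        series, _ = generate(
            single_regime_scenario(rng, noise_sd=3.0, round_to_int=True)
        )
        for s in series:  # construction re-runs the invariant checks
            assert np.all(s.values >= 0) and np.all(s.values <= 100)
            assert len(s) == 52

    def test_bad_regime_ordering_rejected(self, rng):
        scenario = single_regime_scenario(rng)
        regimes = (
            Regime(0.0, scenario.regimes[0].utilities),
            Regime(30.0, scenario.regimes[0].utilities),
            Regime(20.0, scenario.regimes[0].utilities),
        )
        with pytest.raises(ValueError, match="increasing"):
            dataclasses.replace(scenario, regimes=regimes)

    def test_truth_shares_follow_logit(self, rng):
        scenario = single_regime_scenario(rng)
        _, truth = generate(scenario)
        np.testing.assert_allclose(
            truth.shares.S.sum(axis=1) + truth.shares.S0, 1.0, atol=1e-12
        )


class TestTrendsify:
    def test_constant_equal_shares_all_100(self):
        from lvattention.share_model import ShareSystem

        shares = ShareSystem(
            times=np.arange(10, dtype=float),
            topics=("a", "b"),
            S=np.full((10, 2), 0.25),
            S0=np.full(10, 0.5),
        )
        for s in trendsify(shares):
            assert np.allclose(s.values, 100.0)

    def test_linearity(self):
        from lvattention.share_model import ShareSystem

        shares = ShareSystem(
            times=np.arange(10, dtype=float),
            topics=("a", "b"),
            S=np.column_stack([np.full(10, 0.4), np.full(10, 0.2)]),
            S0=np.full(10, 0.4),
        )
        v = {s.topic: s.values for s in trendsify(shares)}
        np.testing.assert_allclose(v["a"], 2.0 * v["b"])

    def test_share_ratios_survive_round_trip(self, rng):
        _, shares = random_fourier_system(rng)
        recovered = to_shares(trendsify(shares), coverage=0.5, floor=1e-9)
        ratio_true = shares.S[:, :, None] / shares.S[:, None, :]
        ratio_back = recovered.S[:, :, None] / recovered.S[:, None, :]
        np.testing.assert_allclose(ratio_back, ratio_true, rtol=1e-12)


class TestParameterRecovery:
    def test_noise_free_recovery_from_truth_shares(self, rng):
        """Noise-free, analysis starting from the true share system: the
        fitted coefficients reproduce the generator's exactly."""
        scenario = single_regime_scenario(rng, order=2)
        _, truth = generate(scenario)
        fitted, diag = fit_utilities(truth.shares, order=3)
        grid = truth.shares.times
        g_true = truth.coeffs.values(grid)
        g_fit = CoefficientSet.from_utilities(fitted, scenario.topics).values(grid)
        assert np.abs(g_true - g_fit).max() < 1e-6
        assert float(diag.share_mse.max()) < 1e-10

    def test_csv_route_recovers_pairwise_differences(self, rng):
        """Through the 0-100 observation scale only relative utilities are
        identified: pairwise coefficient differences are still exact."""
        scenario = single_regime_scenario(rng, order=2)
        series, truth = generate(scenario)
        res = analyze_series(
            series, RunConfig(fit_order=3, floor=1e-9)
        )
        grid = truth.shares.times
        g_true = truth.coeffs.values(grid)
        g_fit = res.report.g
        d_true = g_true[:, :, None] - g_true[:, None, :]
        d_fit = g_fit[:, :, None] - g_fit[:, None, :]
        assert np.abs(d_true - d_fit).max() < 1e-9

    def test_noisy_recovery_sign_agreement(self):
        """Noise sd 2 on the 0-100 scale: role labels still match ground
        truth away from the regime boundary at >= 90% of grid points."""
        scenario = dataclasses.replace(pandemic_preset(), noise_sd=2.0, seed=5)
        series, truth = generate(scenario)
        res = analyze_series(series)
        grid = res.shares.times
        truth_eps = adaptive_eps(truth.coeffs.values(grid))
        truth_report = classify_system(truth.coeffs, grid, eps=truth_eps)
        eligible = np.abs(grid - truth.changepoints[0]) > 2.0
        agree = (res.report.roles == truth_report.roles)[eligible, :]
        assert agree.mean() >= 0.9


class TestPandemicPreset:
    def test_classification_structure_noise_free(self):
        scenario = dataclasses.replace(
            pandemic_preset(), noise_sd=0.0, round_to_int=False
        )
        series, truth = generate(scenario)
        res = analyze_series(series)
        report = res.report
        early = report.role_counts(slice(0, 40))
        assert early[Role.NEUTRALISM] > 0.8 * sum(early.values())
        # weeks 47-50: topic 1 predates all, topics 2-4 in mutualism
        for week in range(47, 51):
            for k, (i, j) in enumerate(report.pairs):
                if i == 0:
                    assert report.roles[week, k] == Role.PREDATOR_PREY
                    assert report.predators[week, k] == "unemployment"
                else:
                    assert report.roles[week, k] == Role.MUTUALISM

    def test_changepoint_detected_near_truth(self):
        scenario = dataclasses.replace(
            pandemic_preset(), noise_sd=0.0, round_to_int=False
        )
        series, truth = generate(scenario)
        res = analyze_series(series)
        intensity = res.report.intensity
        cp = detect_intensification(intensity, window=8)
        assert abs(res.shares.times[cp] - truth.changepoints[0]) <= 2.0

    def test_intensity_ratio_regression(self):
        scenario = dataclasses.replace(
            pandemic_preset(), noise_sd=0.0, round_to_int=False
        )
        series, _ = generate(scenario)
        res = analyze_series(series)
        intensity = res.report.intensity
        ratio = intensity[46:].mean() / intensity[:36].mean()
        assert ratio > 5.0
        # frozen regression value for the fixed preset coefficients
        assert 30.0 < ratio < 120.0


class TestScenarioSerialization:
    def test_round_trip(self, rng):
        scenario = pandemic_preset(noise_sd=1.5, seed=3)
        back = scenario_from_dict(scenario_to_dict(scenario))
        assert back.topics == scenario.topics
        assert back.span == scenario.span
        assert back.noise_sd == scenario.noise_sd
        assert back.seed == scenario.seed
        series1, _ = generate(scenario)
        series2, _ = generate(back)
        assert series1 == series2

    def test_fourier_scenario_round_trip(self, rng):
        scenario = single_regime_scenario(rng)
        back = scenario_from_dict(scenario_to_dict(scenario))
        series1, _ = generate(scenario)
        series2, _ = generate(back)
        assert series1 == series2


class TestBlending:
    def test_blended_utility_is_smooth_at_boundary(self):
        scenario = dataclasses.replace(
            pandemic_preset(), noise_sd=0.0, round_to_int=False
        )
        from lvattention.synthetic_data import blended_utilities

        u = blended_utilities(scenario)[0]
        g = u.derivative()
        t = np.linspace(42.0, 46.0, 4001)
        h = t[1] - t[0]
        fd = np.gradient(np.asarray(u(t)), t)
        np.testing.assert_allclose(np.asarray(g(t))[2:-2], fd[2:-2], atol=1e-4)

    def test_outside_ramp_matches_pieces(self):
        scenario = dataclasses.replace(pandemic_preset(), noise_sd=0.0)
        from lvattention.synthetic_data import blended_utilities

        u = blended_utilities(scenario)[0]
        early_piece = scenario.regimes[0].utilities[0]
        late_piece = scenario.regimes[1].utilities[0]
        assert np.isclose(u(10.0), early_piece(10.0))
        assert np.isclose(u(50.0), late_piece(50.0))
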