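import numpy as np
import pytest

from lvattention.interactions import (
    Role,
    adaptive_eps,
    classify_pair,
    classify_system,
    detect_intensification,
    intensity_profile,
)
from lvattention.lv_dynamics import CoefficientSet, integrate_forward

GRID = np.arange(52, dtype=float)


def constant_coeffs(values, topics=None):
    topics = topics or tuple(f"t{i}" for i in range(len(values)))
    return CoefficientSet(
        topics=topics,
        funcs=tuple((lambda v: (lambda t: v + 0.0 * np.asarray(t)))(v) for v in values),
        provenance="specified",
    )


class TestClassifyPair:
    # exhaustive sign-pattern table {+,0,-}^2
    TABLE = [
        (0.4, 0.2, Role.COMPETITION, None),
        (0.4, -0.2, Role.PREDATOR_PREY, 0),
        (0.4, 0.0, Role.AMENSALISM, None),
        (-0.3, 0.2, Role.PREDATOR_PREY, 1),
        (-0.3, -0.1, Role.MUTUALISM, None),
        (-0.3, 0.0, Role.COMMENSALISM, None),
        (0.0, 0.2, Role.AMENSALISM, None),
        (0.0, -0.1, Role.COMMENSALISM, None),
        (0.0, 0.0, Role.NEUTRALISM, None),
    ]

    @pytest.mark.parametrize("g_a,g_b,role,predator", TABLE)
    def test_truth_table(self, g_a, g_b, role, predator):
        assert classify_pair(g_a, g_b, eps=0.01) == (role, predator)

    def test_near_zero_is_neutralism(self):
        assert classify_pair(0.005, -0.002, eps=0.01) == (Role.NEUTRALISM, None)

    def test_negative_eps_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(0.1, 0.1, eps=-1.0)

    def test_predator_depresses_prey_in_simulation(self):
        """The positive-coefficient topic is the predator: under constant
        g=(0.4, -0.2) topic A's share grows while topic B's is driven down."""
        coeffs = constant_coeffs([0.4, -0.2], topics=("A", "B"))
        times = np.linspace(0.0, 10.0, 50)
        out = integrate_forward(coeffs, np.array([0.3, 0.3]), times)
        assert out.S[-1, 0] > out.S[0, 0]  # predator gains
        assert out.S[-1, 1] < out.S[0, 1]  # prey loses
        role, predator = classify_pair(0.4, -0.2, eps=0.01)
        assert role == Role.PREDATOR_PREY and predator == 0


class TestClassifySystem:
    def test_one_predator_three_mutualists(self):
        coeffs = constant_coeffs(
            [0.5, -0.2, -0.2, -0.2], topics=("u", "s", "n", "p")
        )
        report = classify_system(coeffs, GRID, eps=0.01)
        for k, (i, j) in enumerate(report.pairs):
            if i == 0:
                assert set(report.roles[:, k]) == {Role.PREDATOR_PREY}
                assert set(report.predators[:, k]) == {"u"}
            else:
                assert set(report.roles[:, k]) == {Role.MUTUALISM}

    def test_all_zero_neutralism(self):
        coeffs = constant_coeffs([0.0, 0.0, 0.0])
        report = classify_system(coeffs, GRID, eps=0.01)
        assert set(report.roles.ravel()) == {Role.NEUTRALISM}
        assert np.allclose(report.intensity, 0.0)

    def test_labels_flip_at_analytic_crossing(self):
        # g1(t) = 0.2 * sin(pi (t - 26) / 52) crosses zero exactly at t=26
        coeffs = CoefficientSet(
            topics=("a", "b"),
            funcs=(
                lambda t: 0.2 * np.sin(np.pi * (np.asarray(t) - 26.0) / 52.0),
                lambda t: -0.1 + 0.0 * np.asarray(t),
            ),
            provenance="specified",
        )
        eps = 1e-6
        report = classify_system(coeffs, GRID, eps=eps)
        roles = report.roles[:, 0]
        assert set(roles[:26]) == {Role.MUTUALISM}  # g1 < 0 before 26
        assert roles[26] == Role.COMMENSALISM  # |g1| <= eps exactly at 26
        assert set(roles[27:]) == {Role.PREDATOR_PREY}  # g1 > 0 after

    def test_empty_grid_rejected(self):
        coeffs = constant_coeffs([0.1, 0.2])
        with pytest.raises(ValueError):
            classify_system(coeffs, np.array([]), eps=0.01)

    def test_smoothing_removes_single_flicker(self):
        g1 = np.full(52, 0.3)
        g1[20] = -0.3  # one-point flicker
        coeffs = CoefficientSet(
            topics=("a", "b"),
            funcs=(
                lambda t: g1[np.asarray(t, dtype=int)],
                lambda t: 0.2 + 0.0 * np.asarray(t),
            ),
            provenance="specified",
        )
        rough = classify_system(coeffs, GRID, eps=0.01)
        smooth = classify_system(coeffs, GRID, eps=0.01, smooth_weeks=4)
        assert rough.roles[20, 0] == Role.PREDATOR_PREY
        assert smooth.roles[20, 0] == Role.COMPETITION


class TestIntensity:
    def test_zero(self):
        coeffs = constant_coeffs([0.0, 0.0])
        assert np.allclose(intensity_profile(coeffs, GRID), 0.0)

    def test_constant_sum_of_absolutes(self):
        coeffs = constant_coeffs([0.2, -0.3])
        np.testing.assert_allclose(intensity_profile(coeffs, GRID), 0.5)

    def test_invariant_under_relabeling(self):
        a = constant_coeffs([0.2, -0.3, 0.1], topics=("x", "y", "z"))
        b = constant_coeffs([-0.3, 0.1, 0.2], topics=("y", "z", "x"))
        np.testing.assert_allclose(
            intensity_profile(a, GRID), intensity_profile(b, GRID)
        )


class TestAdaptiveEps:
    def test_scales_with_input(self, rng):
        g = rng.normal(size=(52, 4))
        assert np.isclose(adaptive_eps(3.0 * g), 3.0 * adaptive_eps(g))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adaptive_eps(np.array([]))


def brute_force_changepoint(x, window):
    """Independent exhaustive-scan oracle for detect_intensification."""
    tiny = np.finfo(float).tiny
    ratios = {}
    for k in range(window, len(x) - window + 1):
        lead = np.mean(x[k - window : k])
        trail = np.mean(x[k : k + window])
        ratios[k] = trail / max(lead, tiny)
    best = max(ratios.values())
    return min(k for k, r in ratios.items() if r == best)


class TestDetectIntensification:
    def test_flat_series_earliest_index(self):
        x = np.ones(52)
        assert detect_intensification(x, window=8) == 8

    def test_step_function(self):
        x = np.ones(52)
        x[40:] = 10.0
        assert detect_intensification(x, window=5) == 40

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(10):
            x = rng.uniform(0.1, 5.0, size=60)
            assert detect_intensification(x, 7) == brute_force_changepoint(x, 7)

    def test_monotone_ramp(self):
        x = np.arange(52, dtype=float)
        expected = brute_force_changepoint(x, 8)
        assert detect_intensification(x, window=8) == expected
        assert expected == 8  # ratio decreases along a linear ramp

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            detect_intensification(np.ones(16), window=8)


class TestScaleInvariance:
    def test_classification_invariant_to_positive_scaling_of_inputs(self, rng):
        """Multiplying all raw 0-100 inputs by a positive constant leaves the
        roles unchanged (shares are scale-free)."""
        from conftest import make_series
        from lvattention.pipeline import RunConfig, analyze_series

        values = {t: rng.uniform(5, 90, 30) for t in ("a", "b", "c")}
        series1 = make_series(values)
        series2 = make_series({t: 0.5 * v for t, v in values.items()})
        cfg = RunConfig(fit_order=3)
        rep1 = analyze_series(series1, cfg).report
        rep2 = analyze_series(series2, cfg).report
        assert np.array_equal(rep1.roles, rep2.roles)
        np.testing.assert_allclose(rep1.g, rep2.g, atol=1e-9)
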