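import numpy as np
import pytest

from retroprobe import (
    BiasCurve,
    area_difference,
    bias_group_test,
    relative_orientation,
    sliding_bin_bias,
    wrap_angle,
)
from retroprobe.bias import bin_centers
from retroprobe.synthetic import draw_mixture_errors


def simulate_bias_subject(rng, n, beta, p_mem=0.7, kappa=10.0):
    """Deltas uniform on the circle; mean error beta*sin(delta) via the mixture."""
    deltas = rng.uniform(-np.pi, np.pi, n)
    errors = draw_mixture_errors(n, p_mem, kappa, rng, mu=beta * np.sin(deltas))
    return deltas, errors


class TestRelativeOrientation:
    @pytest.mark.parametrize(
        "other_deg, probed_deg, expected_deg",
        [(30.0, 30.0, 0.0), (10.0, 30.0, -20.0), (350.0, 10.0, -20.0)],
    )
    def test_convention(self, other_deg, probed_deg, expected_deg):
        rel = relative_orientation(np.deg2rad(other_deg), np.deg2rad(probed_deg))
        assert np.rad2deg(rel) == pytest.approx(expected_deg, abs=1e-9)

    def test_antisymmetry(self, rng):
        a, b = rng.uniform(-np.pi, np.pi, (2, 100))
        r_ab = relative_orientation(a, b)
        r_ba = relative_orientation(b, a)
        interior = np.abs(np.abs(r_ab) - np.pi) > 1e-6  # antisymmetric except at ±π
        np.testing.assert_allclose(r_ab[interior], -r_ba[interior], atol=1e-9)


class TestSlidingBinBias:
    def test_geometry(self, rng):
        deltas, errors = simulate_bias_subject(rng, 160, 0.0)
        curve = sliding_bin_bias(deltas, errors)
        assert curve.centers.size == 64
        assert curve.occupancy == 40  # quarter of 160 trials per bin
        spacing = np.diff(curve.centers)
        np.testing.assert_allclose(spacing, 2 * np.pi / 64, atol=1e-12)
        assert (curve.centers > 0).sum() == 32  # half-step offset: clean 32/32 split
        assert not np.any(np.isclose(curve.centers, 0.0))

    def test_constant_error_field(self, rng):
        deltas = rng.uniform(-np.pi, np.pi, 200)
        curve = sliding_bin_bias(deltas, np.full(200, np.deg2rad(5.0)))
        np.testing.assert_allclose(np.rad2deg(curve.mean_bias), 5.0, atol=1e-9)

    def test_harmonic_recovery(self):
        # Quantile bins average sin(delta) over a +/- pi/4 window around each
        # centre, attenuating the first harmonic by sin(w)/w at w = pi/4.
        rng = np.random.default_rng(31)
        beta = np.deg2rad(-5.0)
        deltas, errors = simulate_bias_subject(rng, 20_000, beta, p_mem=1.0, kappa=200.0)
        curve = sliding_bin_bias(deltas, errors)
        X = np.column_stack([np.sin(curve.centers), np.cos(curve.centers)])
        coef, *_ = np.linalg.lstsq(X, curve.mean_bias, rcond=None)
        w = np.pi / 4
        expected = beta * np.sin(w) / w
        assert coef[0] == pytest.approx(expected, rel=0.10)
        assert coef[0] < 0
        assert abs(coef[1]) < abs(coef[0]) / 5  # no spurious even component

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            sliding_bin_bias(np.zeros(4), np.zeros(4))

    def test_shift_equivariance(self, rng):
        deltas, errors = simulate_bias_subject(rng, 300, np.deg2rad(-5.0))
        c = 0.21
        base = sliding_bin_bias(deltas, errors)
        shifted = sliding_bin_bias(deltas, errors + c)
        np.testing.assert_allclose(shifted.mean_bias, base.mean_bias + c, atol=1e-12)
        assert area_difference(shifted).area_diff == pytest.approx(
            area_difference(base).area_diff, abs=1e-12
        )

    def test_reflection_symmetries(self, rng):
        deltas, errors = simulate_bias_subject(rng, 300, np.deg2rad(-5.0))
        base = sliding_bin_bias(deltas, errors)
        # negating the errors alone flips attraction <-> repulsion
        neg_err = sliding_bin_bias(deltas, -errors)
        np.testing.assert_allclose(neg_err.mean_bias, -base.mean_bias, atol=1e-12)
        assert area_difference(neg_err).area_diff == pytest.approx(
            -area_difference(base).area_diff, abs=1e-12
        )
        # mirror reflection (negate deltas AND errors) is the same physical
        # configuration: the curve reverses and negates, and the
        # attraction/repulsion sign is preserved
        refl = sliding_bin_bias(wrap_angle(-deltas), -errors)
        np.testing.assert_allclose(refl.mean_bias, -base.mean_bias[::-1], atol=1e-12)
        assert area_difference(refl).area_diff == pytest.approx(
            area_difference(base).area_diff, abs=1e-12
        )


class TestAreaDifference:
    def _curve(self, values):
        c = bin_centers()
        return BiasCurve(centers=c, mean_bias=np.asarray(values, float), occupancy=2, n_trials=8)

    def test_flat_curve(self):
        assert area_difference(self._curve(np.zeros(64))).area_diff == 0.0

    def test_sine_curve_matches_discrete_oracle(self):
        c = bin_centers()
        stat = area_difference(self._curve(np.sin(c)))
        oracle = np.sin(c[c > 0]).mean() - np.sin(c[c < 0]).mean()  # ~4/pi, attraction
        assert stat.area_diff == pytest.approx(oracle, abs=1e-12)
        assert stat.area_diff > 0
        assert oracle == pytest.approx(4 / np.pi, rel=0.001)  # discrete mean vs integral

    def test_negated_sine_is_repulsion(self):
        c = bin_centers()
        pos = area_difference(self._curve(np.sin(c))).area_diff
        neg = area_difference(self._curve(-np.sin(c))).area_diff
        assert neg == pytest.approx(-pos)
        assert neg < 0


class TestSignRecoveryAndGroupTest:
    @pytest.mark.parametrize("beta_deg, expected_sign", [(-5.0, -1), (5.0, 1)])
    def test_sign_of_area_diff_tracks_injected_bias(self, beta_deg, expected_sign):
        rng = np.random.default_rng(abs(int(beta_deg)) + 100)
        deltas, errors = simulate_bias_subject(rng, 50_000, np.deg2rad(beta_deg))
        stat = area_difference(sliding_bin_bias(deltas, errors))
        assert np.sign(stat.area_diff) == expected_sign

    def test_all_zero_statistics_give_t_zero(self):
        res = bias_group_test(np.zeros(24))
        assert res.statistic == 0.0
        assert res.bf10 < 1.0

    def test_repulsion_detected_across_cohorts(self):
        # 10 cohorts of 24 subjects, 160 trials each, beta = -5 deg
        rng = np.random.default_rng(2024)
        beta = np.deg2rad(-5.0)
        means, pooled = [], []
        for _ in range(10):
            stats = []
            for _ in range(24):
                deltas, errors = simulate_bias_subject(rng, 160, beta)
                stats.append(area_difference(sliding_bin_bias(deltas, errors)).area_diff)
            means.append(np.mean(stats))
            pooled.extend(stats)
        assert sum(m < 0 for m in means) >= 9
        res = bias_group_test(np.asarray(pooled))
        assert res.statistic < 0 and res.p < 1e-6

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            bias_group_test([0.1, 0.2])
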