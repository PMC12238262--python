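"""Trajectory statistics against hand values and naive double-loop oracles."""

import numpy as np
import pytest

from lptraj.core import Trajectory
from lptraj.simulate import simulate_bm
from lptraj.stats import (displacement_moments, displacement_series,
                          ensemble_msd, non_gaussianity,
                          positional_autocorrelation,
                          velocity_autocorrelation,
                          xy_displacement_correlation)

from oracles import oracle_cr, oracle_cv, oracle_moments


# ---------------------------------------------------------------------------
# hand examples
# ---------------------------------------------------------------------------

class TestDisplacementSeries:
    def test_simple(self):
        t = Trajectory([0, 1, 3], [0, 0, 0])
        ds = displacement_series(t, 1)
        np.testing.assert_array_equal(ds.dxs, [1, 2])

    def test_boundary_lag(self):
        t = Trajectory([0, 1, 3], [5, 5, 5])
        ds = displacement_series(t, 2)
        assert len(ds.dxs) == 1 and ds.dxs[0] == 3

    def test_invalid_lag(self):
        t = Trajectory([0, 1, 3], [0, 0, 0])
        with pytest.raises(ValueError):
            displacement_series(t, 3)


class TestMoments:
    def test_alternating_hand_values(self):
        t = Trajectory(np.cumsum([0, 1, -1, 1, -1]), np.zeros(5))
        m = displacement_moments(displacement_series(t, 1))["x"]
        assert m.mean == 0 and m.variance == 1
        assert m.skewness == 0 and m.kurtosis == 1 and m.median == 0

    def test_gaussian_kurtosis(self, rng):
        d = rng.standard_normal(100_000)
        t = Trajectory(np.concatenate([[0], np.cumsum(d)]), np.zeros(100_001))
        m = displacement_moments(displacement_series(t, 1))["x"]
        assert m.kurtosis == pytest.approx(3.0, abs=0.1)

    def test_degenerate_sentinel(self):
        t = Trajectory([0, 2, 4, 6], [0, 0, 0, 0])
        m = displacement_moments(displacement_series(t, 1))["x"]
        assert m.mean == 2 and m.variance == 0
        assert m.skewness == 0 and m.kurtosis == 0 and m.degenerate


class TestVelocityAutocorrelation:
    def test_alternating_steps(self):
        t = Trajectory(np.cumsum([0, 1, -1, 1, -1, 1]), np.zeros(6))
        cv = velocity_autocorrelation(t, 1)
        assert cv[0] == 1.0
        assert cv[1] == pytest.approx(-1.0)

    def test_bm_batch_uncorrelated(self):
        ds = simulate_bm(100, 5000, seed=1)
        cv = velocity_autocorrelation(ds, 2)
        assert abs(cv[1]) < 0.01

    def test_degenerate_zero_curve(self):
        t = Trajectory([1, 1, 1, 1], [0, 0, 0, 0])
        np.testing.assert_array_equal(velocity_autocorrelation(t, 2), 0.0)


class TestPositionalAutocorrelation:
    def test_static_offset_trajectory(self):
        t = Trajectory([1, 1, 1, 1], [0, 0, 0, 0])
        np.testing.assert_allclose(positional_autocorrelation(t, 3), 1.0)

    def test_translation_sensitivity(self, rng):
        """C_v is translation invariant; C_r is not (positions enter
        directly)."""
        pos = rng.standard_normal((1, 2, 30)).cumsum(-1)
        shifted = pos + 50.0
        np.testing.assert_allclose(velocity_autocorrelation(pos, 5),
                                   velocity_autocorrelation(shifted, 5))
        assert not np.allclose(positional_autocorrelation(pos, 5),
                               positional_autocorrelation(shifted, 5))


class TestXYCorrelation:
    def test_perfect_coupling(self, rng):
        xs = rng.standard_normal(50).cumsum()
        assert xy_displacement_correlation(
            Trajectory(xs, xs))[0] == pytest.approx(1.0)
        assert xy_displacement_correlation(
            Trajectory(xs, -xs))[0] == pytest.approx(-1.0)

    def test_independent_components(self, rng):
        t = Trajectory(rng.standard_normal(10_000).cumsum(),
                       rng.standard_normal(10_000).cumsum())
        rho, degenerate = xy_displacement_correlation(t)
        assert not degenerate and abs(rho) < 0.03

    def test_degenerate_component(self):
        rho, degenerate = xy_displacement_correlation(
            Trajectory([0, 1, 2, 3], [5, 5, 5, 5]))
        assert rho == 0.0 and degenerate


class TestNonGaussianity:
    def test_gaussian_is_zero(self, rng):
        pos = np.concatenate([np.zeros((2000, 2, 1)),
                              rng.standard_normal((2000, 2, 199)).cumsum(-1)],
                             axis=-1)
        xi = non_gaussianity(pos, 1)
        assert abs(xi["x"]) < 0.05 and abs(xi["y"]) < 0.05

    def test_two_point_displacements(self, rng):
        """|d| = 1 everywhere: <d^4> = <d^2>^2 = 1, xi = 1/3 - 1 = -2/3."""
        signs = rng.choice([-1.0, 1.0], size=(50, 2, 100))
        pos = np.concatenate([np.zeros((50, 2, 1)), signs.cumsum(-1)], axis=-1)
        xi = non_gaussianity(pos, 1)
        assert xi["x"] == pytest.approx(-2 / 3)

    def test_laplace_displacements(self, rng):
        """Laplace kurtosis is 6, so xi = 6/3 - 1 = 1."""
        d = rng.laplace(size=(500, 2, 200))
        pos = np.concatenate([np.zeros((500, 2, 1)), d.cumsum(-1)], axis=-1)
        xi = non_gaussianity(pos, 1)
        assert xi["x"] == pytest.approx(1.0, abs=0.08)

    def test_scale_invariance(self, rng):
        pos = rng.standard_normal((20, 2, 50)).cumsum(-1)
        a = non_gaussianity(pos, 2)
        b = non_gaussianity(pos * 37.5, 2)
        assert a["x"] == pytest.approx(b["x"]) and a["y"] == pytest.approx(b["y"])


class TestEnsembleMSD:
    def test_bm_curve(self):
        ds = simulate_bm(100, 5000, seed=2)
        es = ensemble_msd(ds, 10)
        np.testing.assert_allclose(es.msd, 2.0 * es.lags, rtol=0.05)

    def test_static_degenerate(self):
        pos = np.zeros((1, 2, 10))
        es = ensemble_msd(pos, 3)
        assert es.degenerate and np.isnan(es.alpha_hat)
        np.testing.assert_array_equal(es.msd, 0.0)


class TestOracleAgreement:
    """Every vectorized functional matches a naive double-loop
    implementation to <= 1e-10 on random small trajectories."""

    def test_autocorrelations_and_moments(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            T = int(rng.integers(5, 21))
            pos = rng.standard_normal((1, 2, T)).cumsum(-1)
            tau_max = min(3, T - 2)
            np.testing.assert_allclose(
                velocity_autocorrelation(pos, tau_max), oracle_cv(pos, tau_max),
                atol=1e-10)
            np.testing.assert_allclose(
                positional_autocorrelation(pos, tau_max), oracle_cr(pos, tau_max),
                atol=1e-10)
            traj = Trajectory(pos[0, 0], pos[0, 1])
            mom = displacement_moments(displacement_series(traj, 1))
            for ci, comp in enumerate("xy"):
                ora = oracle_moments(list(np.diff(pos[0, ci])))
                got = mom[comp]
                for key, val in ora.items():
                    assert abs(getattr(got, key) - val) < 1e-10
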