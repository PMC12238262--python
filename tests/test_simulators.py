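"""Statistical validation of the six diffusion-process simulators.

Each process is checked against an independent statistical oracle: the
closed-form fGn autocovariance, Hill tail-exponent estimates of waiting and
flight times, exact variance laws, and log-log MSD regression.
"""

import numpy as np
import pytest

from lptraj.simulate import (CLASS_ALPHA_RANGES, fgn_autocovariance,
                             make_labeled_dataset, pareto_times, simulate_attm,
                             simulate_bm, simulate_ctrw, simulate_fbm,
                             simulate_lw, simulate_sbm)
from lptraj.stats import ensemble_msd


def hill_tail_exponent(x: np.ndarray, xmin: float = 1.0) -> float:
    """Maximum-likelihood (Hill) estimate of the survival exponent of a
    power-law tail P(X > x) ~ x^-a for x >= xmin."""
    x = x[x >= xmin]
    return len(x) / np.sum(np.log(x / xmin))


@pytest.mark.parametrize("simulate", [
    lambda seed: simulate_bm(50, 4, seed),
    lambda seed: simulate_fbm(0.6, 50, 4, seed),
    lambda seed: simulate_ctrw(0.5, 50, 4, seed),
    lambda seed: simulate_lw(1.5, 50, 4, seed),
    lambda seed: simulate_attm(0.5, 50, 4, seed),
    lambda seed: simulate_sbm(0.5, 50, 4, seed),
])
def test_seed_determinism(simulate):
    np.testing.assert_array_equal(simulate(7).positions(),
                                  simulate(7).positions())


@pytest.mark.parametrize("bad_call", [
    lambda: simulate_fbm(2.5, 50, 1, 0),
    lambda: simulate_ctrw(1.5, 50, 1, 0),
    lambda: simulate_lw(0.5, 50, 1, 0),
    lambda: simulate_attm(1.0, 50, 1, 0),
    lambda: simulate_sbm(-0.1, 50, 1, 0),
    lambda: simulate_bm(1, 1, 0),
])
def test_alpha_and_size_validation(bad_call):
    with pytest.raises(ValueError):
        bad_call()


class TestBrownianMotion:
    def test_msd_is_2dt(self):
        """Per-axis MSD(t) = 2 D t with D = 1/2, i.e. the 2-D MSD is 2 t."""
        ds = simulate_bm(100, 5000, seed=1)
        es = ensemble_msd(ds, 20)
        np.testing.assert_allclose(es.msd, 2.0 * es.lags, rtol=0.05)

    def test_msd_slope_is_one(self):
        ds = simulate_bm(400, 3000, seed=2)
        es = ensemble_msd(ds, 20)
        assert abs(es.alpha_hat - 1.0) < 0.05


class TestFBM:
    def test_h_half_reduces_to_bm(self):
        ds = simulate_fbm(1.0, 200, 2000, seed=3)
        d = np.diff(ds.positions(), axis=-1).reshape(-1, 199)
        ac1 = np.mean(d[:, :-1] * d[:, 1:]) / np.mean(d ** 2)
        assert abs(ac1) < 0.02

    @pytest.mark.parametrize("H", [0.25, 0.75])
    def test_increment_autocorrelation_matches_closed_form(self, H):
        ds = simulate_fbm(2 * H, 200, 2000, seed=4)
        d = np.diff(ds.positions(), axis=-1).reshape(-1, 199)
        ac1 = np.mean(d[:, :-1] * d[:, 1:]) / np.mean(d ** 2)
        expected = fgn_autocovariance(H, np.array([1]))[0]
        assert abs(ac1 - expected) < 0.02

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8])
    def test_msd_exponent(self, alpha):
        ds = simulate_fbm(alpha, 400, 2000, seed=5)
        es = ensemble_msd(ds, 20)
        assert abs(es.alpha_hat - alpha) < 0.1


class TestCTRW:
    def test_zero_order_hold(self):
        """Between renewals every frame-to-frame displacement is exactly 0."""
        ds = simulate_ctrw(0.5, 200, 50, seed=6)
        d = np.diff(ds.positions(), axis=-1)
        moved = np.abs(d).sum(axis=1)
        frac_still = np.mean(moved == 0.0)
        assert frac_still > 0.5  # long waits dominate at alpha = 0.5

    def test_waiting_time_tail_exponent(self):
        draws = pareto_times(0.5, 100_000, np.random.default_rng(7))
        assert abs(hill_tail_exponent(draws) - 0.5) < 0.1

    def test_subdiffusive_msd(self):
        ds = simulate_ctrw(0.5, 200, 2000, seed=8)
        es = ensemble_msd(ds, 20, time_average=False)
        assert es.alpha_hat < 1.0


class TestLevyWalk:
    def test_constant_velocity_within_flight(self):
        """Step vectors repeat within a flight: consecutive equal steps are
        common, and each step magnitude equals the flight speed."""
        ds = simulate_lw(1.5, 200, 20, seed=9)
        d = np.diff(ds.positions(), axis=-1)  # (n, 2, T-1)
        same = np.all(np.isclose(d[:, :, 1:], d[:, :, :-1]), axis=1)
        assert same.mean() > 0.3  # flights longer than one frame exist
        # within runs of equal steps the speed is constant by construction
        speeds = np.linalg.norm(d, axis=1)
        assert np.isfinite(speeds).all()

    def test_flight_duration_tail(self):
        rng = np.random.default_rng(10)
        draws = pareto_times(3.0 - 1.5, 100_000, rng)
        assert abs(hill_tail_exponent(draws) - 1.5) < 0.15

    def test_superdiffusive_msd(self):
        ds = simulate_lw(1.5, 400, 2000, seed=11)
        es = ensemble_msd(ds, 20, time_average=False)
        assert es.alpha_hat > 1.0


class TestATTM:
    def test_segment_displacement_variance(self):
        """For a point mass at D = 0.5 with gamma = 1 every segment lasts
        t = D^-1 = 2 frames and displaces each component by
        sqrt(2 D t) eta: the per-segment displacement variance is
        2 * 0.5 * 2 = 2."""
        ds = simulate_attm(0.5, 201, 1000, seed=12, gamma=1.0, fixed_D=0.5)
        pos = ds.positions()
        seg_disp = pos[:, :, 2::2] - pos[:, :, :-2:2]  # 100 segments each
        assert np.var(seg_disp) == pytest.approx(2.0, rel=0.05)

    def test_single_d_limit_is_gaussian_steps(self):
        """Point mass D = 1, gamma = 1: one-frame segments of variance 2
        per component — i.i.d. Gaussian increments."""
        ds = simulate_attm(0.5, 101, 1000, seed=13, gamma=1.0, fixed_D=1.0)
        d = np.diff(ds.positions(), axis=-1)
        assert np.var(d) == pytest.approx(2.0, rel=0.05)
        # no temporal correlation in the degenerate limit
        cv1 = np.mean(d[:, :, :-1] * d[:, :, 1:]) / np.var(d)
        assert abs(cv1) < 0.01

    def test_subdiffusive_msd(self):
        ds = simulate_attm(0.5, 200, 2000, seed=14)
        es = ensemble_msd(ds, 20, time_average=False)
        assert es.alpha_hat < 1.0


class TestSBM:
    def test_alpha_one_is_bm(self):
        ds = simulate_sbm(1.0, 100, 3000, seed=15)
        d = np.diff(ds.positions(), axis=-1)
        np.testing.assert_allclose(d.var(), 1.0, rtol=0.05)

    def test_exact_variance_law(self):
        """Var(x at frame 4) = 4^0.5 = 2 for sigma^2 = 1, alpha = 0.5."""
        ds = simulate_sbm(0.5, 10, 50_000, seed=16)
        x4 = ds.positions()[:, 0, 4]
        assert np.var(x4) == pytest.approx(2.0, rel=0.05)

    @pytest.mark.parametrize("alpha", [0.5, 1.5])
    def test_msd_exponent_exact_scaling(self, alpha):
        ds = simulate_sbm(alpha, 400, 5000, seed=17)
        es = ensemble_msd(ds, 20, time_average=False)
        assert abs(es.alpha_hat - alpha) < 0.05


class TestComponentIndependence:
    @pytest.mark.parametrize("make", [
        lambda: simulate_bm(200, 2000, seed=18),
        lambda: simulate_fbm(0.5, 200, 2000, seed=18),
        lambda: simulate_sbm(0.5, 200, 2000, seed=18),
    ])
    def test_xy_displacements_uncorrelated(self, make):
        d = np.diff(make().positions(), axis=-1)
        dx, dy = d[:, 0].ravel(), d[:, 1].ravel()
        r = np.corrcoef(dx, dy)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(dx))


class TestBenchmarkBuilder:
    def test_balance_and_normalization(self):
        ds = make_labeled_dataset(n_per_class=10, T=100, seed=19)
        assert len(ds) == 60
        for cls in CLASS_ALPHA_RANGES:
            assert ds.labels.count(cls) == 10
        for t in ds.trajectories:
            assert t.xs[0] == 0.0 and t.ys[0] == 0.0
            steps = np.concatenate([np.diff(t.xs), np.diff(t.ys)])
            assert np.std(steps) == pytest.approx(1.0)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            make_labeled_dataset(("BM", "WEIRD"), n_per_class=2, T=50, seed=0)

    def test_seed_determinism(self):
        a = make_labeled_dataset(n_per_class=5, T=50, seed=20)
        b = make_labeled_dataset(n_per_class=5, T=50, seed=20)
        np.testing.assert_array_equal(a.positions(), b.positions())
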