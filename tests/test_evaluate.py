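"""Fréchet distance, discrepancy tables, quadratic fits, latent sweeps and
condition profiles."""

import numpy as np
import pytest
from scipy.linalg import sqrtm
from scipy.stats import ks_2samp

from lptraj.core import (LabeledTrajectoryDataset, Trajectory,
                         generate_surrogate_lptem)
from lptraj.evaluate import (FeatureDistribution, default_sweep_grid,
                             feature_distribution, frechet_distance,
                             latent_condition_profiles, latent_sweep,
                             quadratic_fit_r2, stat_discrepancy)
from lptraj.nn import Tensor
from lptraj.simulate import simulate_bm, simulate_ctrw
from lptraj.vae import ModelConfig, build_model


class TestFeatureDistribution:
    def test_mean_and_constant_rows(self, rng):
        X = rng.standard_normal((50, 4))
        fd = feature_distribution(X)
        np.testing.assert_allclose(fd.mean, X.mean(axis=0))
        const = feature_distribution(np.ones((10, 3)))
        np.testing.assert_allclose(const.cov, 0.0, atol=1e-15)

    def test_needs_two_samples(self, rng):
        with pytest.raises(ValueError):
            feature_distribution(rng.standard_normal((1, 4)))

    def test_same_distribution_baseline(self, rng):
        """Two large samples of one Gaussian give a near-zero distance —
        the same-class baseline concept."""
        A = feature_distribution(rng.standard_normal((5000, 16)))
        B = feature_distribution(rng.standard_normal((5000, 16)))
        assert frechet_distance(A, B) < 0.5


class TestFrechetDistance:
    def test_identity(self, rng):
        A = feature_distribution(rng.standard_normal((100, 5)))
        # the distance is the sqrt of an O(eps) residual, so tolerance is
        # sqrt-of-machine-precision scale
        assert frechet_distance(A, A) == pytest.approx(0.0, abs=1e-6)

    def test_one_dimensional_closed_form(self):
        """d^2 = (mu1 - mu2)^2 + (sigma1 - sigma2)^2 in 1-D."""
        A = FeatureDistribution(np.array([0.0]), np.array([[1.0]]), 10)
        B = FeatureDistribution(np.array([3.0]), np.array([[4.0]]), 10)
        assert frechet_distance(A, B, return_squared=True) == pytest.approx(10.0)
        assert frechet_distance(A, B) == pytest.approx(np.sqrt(10.0))

    def test_symmetry_and_sqrtm_oracle(self, rng):
        """Agrees with a naive implementation using the matrix square root
        of the covariance product, up to 1e-6, on random PSD pairs."""
        for _ in range(10):
            d = int(rng.integers(2, 10))
            X = rng.standard_normal((80, d)) @ rng.standard_normal((d, d))
            Y = rng.standard_normal((90, d)) + rng.standard_normal(d)
            A, B = feature_distribution(X), feature_distribution(Y)
            d2 = frechet_distance(A, B, return_squared=True)
            naive = float(np.sum((A.mean - B.mean) ** 2) + np.trace(
                A.cov + B.cov - 2 * sqrtm(A.cov @ B.cov).real))
            assert d2 == pytest.approx(naive, abs=1e-6)
            assert frechet_distance(A, B) == pytest.approx(
                frechet_distance(B, A), abs=1e-8)

    def test_dimension_mismatch_and_indefinite(self, rng):
        A = feature_distribution(rng.standard_normal((20, 3)))
        B = feature_distribution(rng.standard_normal((20, 4)))
        with pytest.raises(ValueError):
            frechet_distance(A, B)
        bad = FeatureDistribution(np.zeros(2), np.array([[1.0, 0.0],
                                                         [0.0, -1.0]]), 10)
        ok = FeatureDistribution(np.zeros(2), np.eye(2), 10)
        with pytest.raises(np.linalg.LinAlgError):
            frechet_distance(bad, ok)


class TestStatDiscrepancy:
    def test_self_comparison_is_zero(self):
        ds = simulate_bm(100, 50, seed=1)
        table = stat_discrepancy(ds, ds)
        assert all(v == 0.0 for v in table.values())

    def test_unit_weights_match_unweighted(self):
        a = simulate_bm(100, 50, seed=2)
        b = simulate_bm(100, 50, seed=3)
        table = stat_discrepancy(a, b)
        assert table["total_weighted"] <= table["total_unweighted"]
        from lptraj.loss import LossWeights
        unit = LossWeights(mse=1.0)  # statistic weights already 1
        table_unit = stat_discrepancy(a, b, weights=unit)
        assert table_unit["total_weighted"] == pytest.approx(
            table_unit["total_unweighted"])

    def test_heavy_tailed_class_differs_in_kurtosis(self):
        bm = simulate_bm(200, 2000, seed=4)
        ctrw = simulate_ctrw(0.2, 200, 2000, seed=5)
        table = stat_discrepancy(bm, ctrw)
        assert table["kurt"] > 0.0


class TestQuadraticFit:
    def test_exact_quadratic(self):
        x = np.linspace(-2, 2, 9)
        fit = quadratic_fit_r2(x, 3 * x ** 2 - x + 0.5)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coefficients[0] == pytest.approx(3.0)

    def test_constant_y_flagged(self):
        fit = quadratic_fit_r2([0, 1, 2, 3], [5, 5, 5, 5])
        assert fit.degenerate and np.isnan(fit.r2)

    def test_validation(self):
        with pytest.raises(ValueError):
            quadratic_fit_r2([1, 2], [1, 2])
        with pytest.raises(ValueError):
            quadratic_fit_r2([1, 1, 1], [1, 2, 3])

    def test_matches_normal_equations_oracle(self, rng):
        """Coefficients agree with an explicit normal-equations solve."""
        x = rng.uniform(-3, 3, 50)
        y = 1.5 * x ** 2 - 0.7 * x + 2 + 0.3 * rng.standard_normal(50)
        fit = quadratic_fit_r2(x, y)
        V = np.column_stack([x ** 2, x, np.ones_like(x)])
        beta = np.linalg.solve(V.T @ V, V.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)


class _QuadraticDecoder:
    """Mock decoder whose measured C_v(1) is an exact function of z_i that
    lies on a quadratic: steps decay geometrically with ratio r(z_i), and
    for |r| < 1 the lag-1 velocity autocorrelation equals r up to a
    sub-1e-12 truncation term."""

    latent_dim = 12
    T = 120

    class config:
        latent_dim = 12

    def __init__(self, index):
        self.index = index

    def decode_tensors(self, z):
        zz = z.data
        r = 0.05 * zz[:, self.index] ** 2 + 0.1 * zz[:, self.index] + 0.2
        t = np.arange(self.T - 1)
        steps = r[:, None] ** t[None, :]
        steps = np.stack([steps, steps], axis=1)
        pos = np.concatenate([np.zeros((len(zz), 2, 1)), steps.cumsum(-1)],
                             axis=-1)
        return Tensor(pos)


class _NullDecoder(_QuadraticDecoder):
    """Statistic numerically independent of z_i: pseudo-random wiggles that
    a quadratic cannot fit."""

    def decode_tensors(self, z):
        zz = z.data
        r = 0.3 + 0.2 * np.sin(997.0 * zz[:, self.index])
        t = np.arange(self.T - 1)
        steps = np.stack([r[:, None] ** t[None, :]] * 2, axis=1)
        pos = np.concatenate([np.zeros((len(zz), 2, 1)), steps.cumsum(-1)],
                             axis=-1)
        return Tensor(pos)


class TestLatentSweep:
    def test_default_grid_contract(self):
        grid = default_sweep_grid()
        assert len(grid) == 13
        assert grid[0] == -3.0 and grid[-1] == 3.0
        np.testing.assert_allclose(np.diff(grid), 0.5)

    def test_exact_quadratic_relation_gives_r2_one(self):
        res = latent_sweep(_QuadraticDecoder(2), 2, n_per_point=50, seed=0)
        assert res.r2["cv1_x"] > 1 - 1e-9

    def test_null_relation_gives_low_r2(self):
        grid = np.linspace(-3, 3, 41)
        res = latent_sweep(_NullDecoder(2), 2, grid, n_per_point=50, seed=0)
        assert res.r2["cv1_x"] < 0.3

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            latent_sweep(_QuadraticDecoder(0), 0, np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            latent_sweep(_QuadraticDecoder(0), 0, np.array([-4, 0, 4.0]))
        with pytest.raises(ValueError):
            latent_sweep(_QuadraticDecoder(0), 99)


@pytest.fixture(scope="module")
def tiny_vae():
    return build_model(ModelConfig(T=200, embed_dim=8, n_heads=2,
                                   patch=10, seed=0))


class TestConditionProfiles:
    def make_long(self, seed, condition, n=4, T=1000):
        ds = generate_surrogate_lptem(n, T, seed=seed)
        for t in ds.trajectories:
            t.meta["condition"] = condition
        return ds.trajectories

    def test_segment_bookkeeping(self, tiny_vae):
        """Eight 4000-frame trajectories -> 20 segments each -> 160 latent
        mean vectors."""
        trajs = self.make_long(1, "dose20", n=8, T=4000)
        prof = latent_condition_profiles(tiny_vae, trajs)
        assert prof.conditions == ("dose20",)
        assert prof.mu["dose20"].shape == (160, 12)
        assert prof.mu_nongauss["dose20"].shape == (160,)

    def test_average_of_two_latent_means(self, tiny_vae):
        trajs = self.make_long(2, "c", n=2, T=600)
        prof = latent_condition_profiles(tiny_vae, trajs)
        i, j = prof.nongauss_indices
        np.testing.assert_allclose(
            prof.mu_nongauss["c"],
            0.5 * (prof.mu["c"][:, i] + prof.mu["c"][:, j]))

    def test_untagged_grouping(self, tiny_vae):
        ds = generate_surrogate_lptem(2, 400, seed=3)
        prof = latent_condition_profiles(tiny_vae, ds.trajectories)
        assert prof.conditions == ("untagged",)

    def test_identical_conditions_indistinguishable(self, tiny_vae):
        """Two groups drawn from the same process yield statistically
        indistinguishable latent-mean distributions (two-sample KS)."""
        a = self.make_long(4, "g1", n=6, T=1200)
        b = self.make_long(5, "g2", n=6, T=1200)
        prof = latent_condition_profiles(tiny_vae, a + b)
        stat, p = ks_2samp(prof.mu_nongauss["g1"], prof.mu_nongauss["g2"])
        assert p > 0.1

    def test_too_short_trajectory_rejected(self, tiny_vae):
        ds = generate_surrogate_lptem(1, 100, seed=6)
        with pytest.raises(ValueError):
            latent_condition_profiles(tiny_vae, ds.trajectories)
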