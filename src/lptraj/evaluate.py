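"""Evaluation of generative quality and latent-space interpretation.

Four tools:

* the Fréchet distance between Gaussian fits to classifier-feature
  distributions (the FID construction transplanted from images to
  trajectories),
* ensemble statistic-discrepancy tables between two trajectory batches,
* latent sweeps — decode while sliding one latent coordinate across
  +-3 SD of the prior and quantify, via a quadratic fit's R^2, how strongly
  that coordinate controls the non-Gaussianity xi(1) and the velocity
  autocorrelation C_v(1) of the generated ensemble,
* condition-wise latent profiles: segment long trajectories, encode each
  segment and collect the posterior means that track non-Gaussianity
  (mu_1, mu_5 — reported through their average) and anticorrelation (mu_4)
  per experimental condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stats as tstats
from .core import LabeledTrajectoryDataset, Trajectory, segment_trajectory
from .loss import LossWeights

__all__ = [
    "FeatureDistribution", "QuadraticFit", "SweepResult", "LatentProfile",
    "feature_distribution", "frechet_distance", "stat_discrepancy",
    "quadratic_fit_r2", "latent_sweep", "latent_condition_profiles",
]


@dataclass(frozen=True)
class FeatureDistribution:
    """Gaussian summary (mean, covariance) of a feature sample."""

    mean: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self):
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if self.n < 2:
            raise ValueError("need at least 2 samples")


def feature_distribution(features: np.ndarray) -> FeatureDistribution:
    """Sample mean and (1/(n-1)) covariance of an (n, d) feature matrix."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need an (n >= 2, d) feature matrix")
    mean = features.mean(axis=0)
    cov = np.cov(features, rowvar=False)
    cov = 0.5 * (cov + cov.T)
    return FeatureDistribution(mean=mean, cov=np.atleast_2d(cov),
                               n=features.shape[0])


def frechet_distance(A: FeatureDistribution, B: FeatureDistribution,
                     *, return_squared: bool = False) -> float:
    """Fréchet (Wasserstein-2) distance between two Gaussian summaries.

    d^2 = ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^(1/2)).

    The matrix square root is taken symmetrically: with R = S_a^(1/2),
    Tr((S_a S_b)^(1/2)) = sum of sqrt of the eigenvalues of R S_b R, which
    are real for PSD inputs.  Small negative eigenvalues (within
    1e-6 * lambda_max) are clamped to zero; larger negativity raises.
    """
    if A.mean.shape != B.mean.shape:
        raise ValueError("feature dimensions differ")
    diff = A.mean - B.mean
    root_a = _psd_sqrt(A.cov, "A")
    inner = root_a @ B.cov @ root_a
    inner = 0.5 * (inner + inner.T)
    eig = np.linalg.eigvalsh(inner)
    eig = _clamp_spectrum(eig, "sqrt(S_a S_b)")
    d2 = float(diff @ diff + np.trace(A.cov) + np.trace(B.cov)
               - 2.0 * np.sum(np.sqrt(eig)))
    d2 = max(d2, 0.0)  # guard tiny negative round-off
    return d2 if return_squared else float(np.sqrt(d2))


def _clamp_spectrum(eig: np.ndarray, what: str) -> np.ndarray:
    lam_max = max(float(eig.max()), 0.0)
    tol = 1e-6 * max(lam_max, 1e-30)
    if (eig < -tol).any():
        raise np.linalg.LinAlgError(
            f"{what} is strongly indefinite: min eigenvalue {eig.min():.3e} "
            f"vs tolerance {-tol:.3e}")
    return np.clip(eig, 0.0, None)


def _psd_sqrt(S: np.ndarray, what: str) -> np.ndarray:
    eig, vec = np.linalg.eigh(S)
    eig = _clamp_spectrum(eig, what)
    return (vec * np.sqrt(eig)) @ vec.T


# ---------------------------------------------------------------------------
# statistic-discrepancy table
# ---------------------------------------------------------------------------

def _ensemble_averages(batch, tau_max: int) -> dict[str, float]:
    """Ensemble averages of every loss statistic over a trajectory batch."""
    pos = batch.positions() if isinstance(batch, LabeledTrajectoryDataset) \
        else np.asarray(batch, dtype=float)
    d = np.diff(pos, axis=-1)
    mu = d.mean(axis=-1, keepdims=True)
    c = d - mu
    var = (c ** 2).mean(axis=-1)
    sd = np.sqrt(var)
    ok = sd > 0
    skew = np.zeros_like(var)
    kurt = np.zeros_like(var)
    skew[ok] = ((c ** 3).mean(axis=-1))[ok] / sd[ok] ** 3
    kurt[ok] = ((c ** 4).mean(axis=-1))[ok] / var[ok] ** 2
    out = {
        "mean": float(mu.mean()),
        "var": float(var.mean()),
        "skew": float(skew.mean()),
        "kurt": float(kurt.mean()),
        "median": float(np.median(d, axis=-1).mean()),
    }
    denom = sd[:, 0] * sd[:, 1]
    rho = np.zeros(len(d))
    okxy = denom > 0
    rho[okxy] = (c[:, 0] * c[:, 1]).mean(axis=-1)[okxy] / denom[okxy]
    out["xy"] = float(rho.mean())
    cv = tstats.velocity_autocorrelation(pos, min(tau_max, d.shape[-1] - 1))
    cr = tstats.positional_autocorrelation(pos, min(tau_max, pos.shape[-1] - 1))
    out["cv"] = float(cv[1:].mean())
    out["cr"] = float(cr[1:].mean())
    return out


def stat_discrepancy(batch_a, batch_b,
                     weights: LossWeights | None = None,
                     tau_max: int | None = None) -> dict[str, float]:
    """Squared differences of ensemble-averaged loss statistics.

    For every statistic in the physics-informed loss, computes its ensemble
    average over each batch and the squared difference of the two averages;
    returns the per-term table plus ``total_unweighted`` and
    ``total_weighted`` (using the loss weights).
    """
    weights = weights or LossWeights()
    tau_max = tau_max or weights.tau_max
    avg_a = _ensemble_averages(batch_a, tau_max)
    avg_b = _ensemble_averages(batch_b, tau_max)
    table = {k: (avg_a[k] - avg_b[k]) ** 2 for k in avg_a}
    table["total_unweighted"] = float(sum(table[k] for k in avg_a))
    table["total_weighted"] = float(
        sum(getattr(weights, k) * table[k] for k in avg_a))
    return table


# ---------------------------------------------------------------------------
# quadratic fits and latent sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares degree-2 fit with explained-variance summary."""

    coefficients: tuple[float, float, float]  # a x^2 + b x + c
    ss_res: float
    ss_tot: float
    r2: float
    degenerate: bool = False


def quadratic_fit_r2(x, y) -> QuadraticFit:
    """Fit y ~ a x^2 + b x + c and report R^2 = 1 - SS_res / SS_tot.

    Constant y (SS_tot = 0) yields a flagged fit with nan R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("x values must not all be equal")
    coeffs = np.polyfit(x, y, 2)
    y_fit = np.polyval(coeffs, x)
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return QuadraticFit(tuple(coeffs), ss_res, 0.0, float("nan"),
                            degenerate=True)
    return QuadraticFit(tuple(coeffs), ss_res, ss_tot, 1.0 - ss_res / ss_tot)


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-point ensemble statistics of one latent coordinate sweep."""

    latent_index: int
    grid: np.ndarray
    stats: dict[str, np.ndarray]       # statistic name -> value per grid point
    fits: dict[str, QuadraticFit] = field(default_factory=dict)

    @property
    def r2(self) -> dict[str, float]:
        return {k: f.r2 for k, f in self.fits.items()}


def default_sweep_grid(n_points: int = 13) -> np.ndarray:
    """Evenly spaced grid over [-3, +3] (prior SD units), endpoints included."""
    return np.linspace(-3.0, 3.0, n_points)


def latent_sweep(model, latent_index: int, grid: np.ndarray | None = None,
                 n_per_point: int = 1000, *, seed: int = 0) -> SweepResult:
    """Sweep one latent coordinate and quantify what it encodes.

    For each grid value, ``n_per_point`` trajectories are decoded from
    latent vectors whose non-swept coordinates are drawn once per
    trajectory from N(0, 1) (fixed across grid points, so points differ
    only in the swept coordinate).  Per point, the ensemble non-Gaussianity
    xi(1) and velocity autocorrelation C_v(1) are computed per component
    and summarized by a quadratic fit's R^2 over the grid.

    ``model`` needs a ``decode_tensors``-compatible surface (anything with
    ``config.latent_dim`` and a ``decode_tensors(Tensor) -> Tensor``); the
    trained trajectory VAE and the mock decoders used in testing both
    qualify.
    """
    from .nn import Tensor

    grid = default_sweep_grid() if grid is None else np.asarray(grid, float)
    if grid.ndim != 1 or len(grid) < 3 or not (np.diff(grid) > 0).all():
        raise ValueError("grid must be strictly increasing with >= 3 points")
    if grid.min() < -3.0 - 1e-9 or grid.max() > 3.0 + 1e-9:
        raise ValueError("grid must lie within [-3, 3]")
    latent_dim = model.config.latent_dim
    if not 0 <= latent_index < latent_dim:
        raise ValueError("latent index out of range")
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n_per_point, latent_dim))
    stats: dict[str, list[float]] = {k: [] for k in
                                     ("xi_x", "xi_y", "cv1_x", "cv1_y")}
    for val in grid:
        z = base.copy()
        z[:, latent_index] = val
        out = model.decode_tensors(Tensor(z)).data   # (n, 2, T)
        xi = tstats.non_gaussianity(out, tau=1)
        stats["xi_x"].append(xi["x"])
        stats["xi_y"].append(xi["y"])
        d = np.diff(out, axis=-1)
        for ci, comp in enumerate("xy"):
            v = d[:, ci]
            denom = np.mean(v ** 2)
            cv1 = np.mean(v[:, :-1] * v[:, 1:]) / denom if denom else 0.0
            stats[f"cv1_{comp}"].append(float(cv1))
    arrays = {k: np.asarray(v) for k, v in stats.items()}
    fits = {k: quadratic_fit_r2(grid, v) for k, v in arrays.items()}
    return SweepResult(latent_index=latent_index, grid=grid, stats=arrays,
                       fits=fits)


# ---------------------------------------------------------------------------
# condition-wise latent profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentProfile:
    """Per-condition distributions of segment-wise posterior means."""

    conditions: tuple[str, ...]
    mu: dict[str, np.ndarray]           # condition -> (n_segments, latent_dim)
    mu_nongauss: dict[str, np.ndarray]  # condition -> <mu_1, mu_5> per segment
    mu_anticorr: dict[str, np.ndarray]  # condition -> mu_4 per segment
    nongauss_indices: tuple[int, int]
    anticorr_index: int


def latent_condition_profiles(model, trajectories: list[Trajectory], *,
                              segment_length: int = 200,
                              nongauss_indices: tuple[int, int] = (0, 4),
                              anticorr_index: int = 3,
                              condition_key: str = "condition",
                              normalize: bool = True) -> LatentProfile:
    """Segment long trajectories, encode the pieces, group latent means by
    condition.

    Latent coordinates are addressed 0-based: the defaults (0, 4) and 3
    are the first, fifth and fourth latent dimensions — the coordinates
    that track non-Gaussianity and anticorrelation in this architecture's
    convention.  The non-Gaussianity summary per segment is the arithmetic
    mean of the two chosen posterior means.  Trajectories without the
    condition tag are grouped under ``"untagged"``.
    """
    from .core import normalize_trajectory
    from .vae import encode

    groups: dict[str, list[Trajectory]] = {}
    for traj in trajectories:
        if len(traj) < segment_length:
            raise ValueError("trajectory shorter than one segment")
        cond = str(traj.meta.get(condition_key, "untagged"))
        for seg in segment_trajectory(traj, segment_length):
            if normalize:
                seg, _ = normalize_trajectory(seg)
            groups.setdefault(cond, []).append(seg)
    i, j = nongauss_indices
    mu, mu_ng, mu_ac = {}, {}, {}
    for cond, segs in groups.items():
        code = encode(model, LabeledTrajectoryDataset(segs, ["?"] * len(segs)))
        mu[cond] = code.mu
        mu_ng[cond] = 0.5 * (code.mu[:, i] + code.mu[:, j])
        mu_ac[cond] = code.mu[:, anticorr_index]
    return LatentProfile(conditions=tuple(sorted(groups)), mu=mu,
                         mu_nongauss=mu_ng, mu_anticorr=mu_ac,
                         nongauss_indices=nongauss_indices,
                         anticorr_index=anticorr_index)
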