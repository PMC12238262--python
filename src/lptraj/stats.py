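"""Statistical functionals of single-particle trajectories.

These are the quantities that enter the physics-informed training loss and
the downstream analyses: displacement moments and median, velocity and
positional autocorrelation curves, the x-y displacement correlation, the
ensemble non-Gaussianity parameter xi(tau), and the ensemble mean squared
displacement with its fitted anomalous exponent.

Conventions
-----------
* Moments use the population (1/n) normalization, matching the expectation
  notation they implement; kurtosis is non-excess (Gaussian = 3).
* Single-trajectory time averages run over every valid start time
  (maximum overlap).
* The velocity at frame t is identified with the lag-1 displacement
  r(t+1) - r(t); no separate velocity timescale is introduced.
* Zero-variance inputs are flagged as degenerate rather than producing
  non-finite values: skewness and kurtosis are reported as 0 and
  autocorrelation curves as all-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabeledTrajectoryDataset, Trajectory

__all__ = [
    "DisplacementSeries", "Moments", "StatVector", "EnsembleStats",
    "displacement_series", "displacement_moments", "velocity_autocorrelation",
    "positional_autocorrelation", "xy_displacement_correlation",
    "non_gaussianity", "ensemble_msd", "stat_vector",
]


@dataclass(frozen=True)
class DisplacementSeries:
    """Per-component displacements of one trajectory at a fixed lag."""

    dxs: np.ndarray
    dys: np.ndarray
    lag: int


@dataclass(frozen=True)
class Moments:
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    median: float
    degenerate: bool = False


@dataclass(frozen=True)
class StatVector:
    """Per-trajectory statistical fingerprint used by the training loss."""

    x: Moments
    y: Moments
    xy_corr: float
    cv_curve: np.ndarray
    cr_curve: np.ndarray


@dataclass(frozen=True)
class EnsembleStats:
    msd: np.ndarray          # MSD(tau), tau = 1..max_lag
    lags: np.ndarray
    alpha_hat: float         # log-log slope; nan when degenerate
    degenerate: bool = False


def _positions(obj) -> np.ndarray:
    """Coerce a Trajectory / dataset / (n, 2, T) array to (n, 2, T)."""
    if isinstance(obj, Trajectory):
        return np.stack([obj.xs, obj.ys])[None]
    if isinstance(obj, LabeledTrajectoryDataset):
        return obj.positions()
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1] != 2:
        raise ValueError("expected Trajectory, dataset, or (n, 2, T) array")
    return arr


def displacement_series(traj: Trajectory, lag: int = 1) -> DisplacementSeries:
    """Displacements dr(t) = r(t + lag) - r(t) for every valid t."""
    T = len(traj)
    if not 1 <= lag <= T - 1:
        raise ValueError(f"lag must be in [1, {T - 1}]")
    return DisplacementSeries(traj.xs[lag:] - traj.xs[:-lag],
                              traj.ys[lag:] - traj.ys[:-lag], lag)


def _moments_1d(d: np.ndarray) -> Moments:
    if d.size == 0:
        raise ValueError("empty displacement series")
    mu = float(np.mean(d))
    var = float(np.mean((d - mu) ** 2))
    med = float(np.median(d))
    if var == 0.0:
        return Moments(mu, 0.0, 0.0, 0.0, med, degenerate=True)
    sd = np.sqrt(var)
    skew = float(np.mean((d - mu) ** 3) / sd ** 3)
    kurt = float(np.mean((d - mu) ** 4) / var ** 2)
    return Moments(mu, var, skew, kurt, med)


def displacement_moments(ds: DisplacementSeries) -> dict[str, Moments]:
    """Population mean/variance/skewness/kurtosis/median per component."""
    return {"x": _moments_1d(np.asarray(ds.dxs)),
            "y": _moments_1d(np.asarray(ds.dys))}


def velocity_autocorrelation(obj, tau_max: int) -> np.ndarray:
    """Normalized velocity autocorrelation curve C_v(tau), tau = 0..tau_max.

    C_v(tau) = <v(t) . v(t+tau)> / <v(t)^2> with the 2-D dot product, the
    average running over all valid start frames — and over trajectories
    when a batch is given.  A zero-velocity input yields an all-zero curve.
    """
    pos = _positions(obj)
    v = np.diff(pos, axis=-1)                 # (n, 2, T-1)
    n_v = v.shape[-1]
    if not 0 <= tau_max <= n_v - 1:
        raise ValueError(f"tau_max must be in [0, {n_v - 1}]")
    denom = np.mean((v ** 2).sum(axis=1))
    if denom == 0.0:
        return np.zeros(tau_max + 1)
    out = np.empty(tau_max + 1)
    for tau in range(tau_max + 1):
        if tau == 0:
            out[0] = 1.0
        else:
            prod = (v[:, :, :-tau] * v[:, :, tau:]).sum(axis=1)
            out[tau] = prod.mean() / denom
    return out


def positional_autocorrelation(obj, tau_max: int) -> np.ndarray:
    """Normalized positional autocorrelation C_r(tau), tau = 0..tau_max.

    C_r(tau) = <r(t) . r(t+tau)> / <r(t)^2> over all valid start frames.
    Positions enter directly, so the curve is *not* translation invariant.
    An all-origin input yields an all-zero curve.
    """
    pos = _positions(obj)
    T = pos.shape[-1]
    if not 0 <= tau_max <= T - 1:
        raise ValueError(f"tau_max must be in [0, {T - 1}]")
    denom = np.mean((pos ** 2).sum(axis=1))
    if denom == 0.0:
        return np.zeros(tau_max + 1)
    out = np.empty(tau_max + 1)
    for tau in range(tau_max + 1):
        if tau == 0:
            out[0] = 1.0
        else:
            prod = (pos[:, :, :-tau] * pos[:, :, tau:]).sum(axis=1)
            out[tau] = prod.mean() / denom
    return out


def xy_displacement_correlation(traj: Trajectory) -> tuple[float, bool]:
    """Pearson correlation between lag-1 x and y displacements.

    Returns ``(rho, degenerate)``; a zero-variance component gives
    ``(0.0, True)``.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 frames")
    dx = np.diff(traj.xs)
    dy = np.diff(traj.ys)
    sx = dx.std()
    sy = dy.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0, True
    rho = float(np.mean((dx - dx.mean()) * (dy - dy.mean())) / (sx * sy))
    return rho, False


def non_gaussianity(obj, tau: int = 1) -> dict[str, float]:
    """Ensemble non-Gaussianity xi(tau) per component.

    xi = (1/3) <dr^4> / <dr^2>^2 - 1, with the moments pooled over every
    lag-tau displacement of every trajectory; 0 for Gaussian displacements.
    """
    pos = _positions(obj)
    if pos.shape[0] == 0:
        raise ValueError("empty batch")
    T = pos.shape[-1]
    if not 1 <= tau <= T - 1:
        raise ValueError(f"tau must be in [1, {T - 1}]")
    d = pos[:, :, tau:] - pos[:, :, :-tau]    # (n, 2, T-tau)
    out = {}
    for ci, comp in enumerate("xy"):
        dc = d[:, ci].ravel()
        m2 = np.mean(dc ** 2)
        if m2 == 0.0:
            raise ValueError(f"zero second moment in component {comp}")
        out[comp] = float(np.mean(dc ** 4) / (3.0 * m2 ** 2) - 1.0)
    return out


def ensemble_msd(obj, max_lag: int, time_average: bool = True) -> EnsembleStats:
    """Ensemble MSD curve and fitted anomalous exponent.

    MSD(tau) is the mean squared displacement *magnitude* (x and y summed)
    at lag tau, averaged over trajectories and — when ``time_average`` is
    true — over all start times.  For ageing (non-stationary) processes
    such as scaled Brownian motion or a CTRW, the time-averaged curve does
    not follow the t^alpha law; pass ``time_average=False`` to measure
    displacements from the first frame instead, which recovers the
    ensemble scaling.  alpha_hat is the least-squares slope of log MSD vs
    log tau over lags 1..max_lag; a zero MSD yields a flagged, nan-exponent
    result.
    """
    pos = _positions(obj)
    T = pos.shape[-1]
    if pos.shape[0] == 0:
        raise ValueError("empty batch")
    if T < 3:
        raise ValueError("need at least 3 frames")
    if not 1 <= max_lag <= T - 1:
        raise ValueError(f"max_lag must be in [1, {T - 1}]")
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    if time_average:
        for i, tau in enumerate(lags):
            d = pos[:, :, tau:] - pos[:, :, :-tau]
            msd[i] = (d ** 2).sum(axis=1).mean()
    else:
        d = pos[:, :, 1:max_lag + 1] - pos[:, :, :1]
        msd[:] = (d ** 2).sum(axis=1).mean(axis=0)
    positive = msd > 0.0
    if positive.sum() < 2:
        return EnsembleStats(msd, lags, float("nan"), degenerate=True)
    alpha_hat = float(np.polyfit(np.log(lags[positive]),
                                 np.log(msd[positive]), 1)[0])
    return EnsembleStats(msd, lags, alpha_hat, degenerate=not positive.all())


def stat_vector(traj: Trajectory, tau_max: int = 25) -> StatVector:
    """The full per-trajectory fingerprint used by the training objective."""
    ds = displacement_series(traj, 1)
    mom = displacement_moments(ds)
    rho, _ = xy_displacement_correlation(traj)
    tv = min(tau_max, len(traj) - 2)
    tr = min(tau_max, len(traj) - 1)
    return StatVector(x=mom["x"], y=mom["y"], xy_corr=rho,
                      cv_curve=velocity_autocorrelation(traj, tv),
                      cr_curve=positional_autocorrelation(traj, tr))
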