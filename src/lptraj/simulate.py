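"""Seeded simulators for six benchmark stochastic diffusion processes.

All generators produce 2-D trajectories with independent x and y components
(the Lévy walk couples them only through the shared flight heading) and
return a :class:`~lptraj.core.LabeledTrajectoryDataset`.  The processes and
their admissible anomalous exponents follow the AnDi-challenge benchmark
conventions:

========  ===========================================  ==================
process   increments                                   MSD scaling
========  ===========================================  ==================
BM        i.i.d. standard normal                       ~ t
FBM       fractional Gaussian noise, H = alpha/2       ~ t^alpha
CTRW      renewal jumps after power-law waits          subdiffusive
LW        constant-velocity flights, power-law length  superdiffusive
ATTM      piecewise diffusivity D_i, t_i = D_i^-gamma  subdiffusive
SBM       Gaussian steps with D(t) ~ t^(alpha-1)       ~ t^alpha (exact)
========  ===========================================  ==================
"""

from __future__ import annotations

import numpy as np

from .core import (DegenerateTrajectoryError, LabeledTrajectoryDataset,
                   Trajectory, normalize_trajectory)

__all__ = [
    "simulate_bm", "simulate_fbm", "simulate_ctrw", "simulate_lw",
    "simulate_attm", "simulate_sbm", "make_labeled_dataset",
    "fgn", "CLASS_ALPHA_RANGES", "SIMULATED_CLASSES",
]

SIMULATED_CLASSES = ("BM", "FBM", "CTRW", "LW", "ATTM", "SBM")

#: per-class uniform sampling range of the anomalous exponent alpha used by
#: the balanced benchmark builder (BM has no exponent).
CLASS_ALPHA_RANGES: dict[str, tuple[float, float]] = {
    "BM": (1.0, 1.0),
    "FBM": (0.1, 1.0),
    "CTRW": (0.1, 1.0),
    "LW": (1.0, 2.0),
    "ATTM": (0.1, 1.0),
    "SBM": (0.1, 1.0),
}


def _check_T_n(T: int, n: int) -> None:
    if T < 2:
        raise ValueError("T must be >= 2")
    if n < 1:
        raise ValueError("n must be >= 1")


def _dataset(pos: np.ndarray, label: str) -> LabeledTrajectoryDataset:
    trajs = [Trajectory(pos[i, 0], pos[i, 1]) for i in range(pos.shape[0])]
    return LabeledTrajectoryDataset(trajs, [label] * pos.shape[0])


# ---------------------------------------------------------------------------
# Brownian motion
# ---------------------------------------------------------------------------

def simulate_bm(T: int, n: int, seed: int) -> LabeledTrajectoryDataset:
    """Brownian motion: cumulative sums of i.i.d. standard-normal steps.

    Per component the step variance is 1, i.e. D = 1/2 and the per-axis
    ensemble MSD is t.
    """
    _check_T_n(T, n)
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n, 2, T - 1))
    pos = np.concatenate([np.zeros((n, 2, 1)), np.cumsum(steps, axis=-1)], axis=-1)
    return _dataset(pos, "BM")


# ---------------------------------------------------------------------------
# fractional Brownian motion
# ---------------------------------------------------------------------------

def fgn_autocovariance(H: float, lags: np.ndarray) -> np.ndarray:
    """Closed-form autocovariance of unit-variance fractional Gaussian noise:
    ``0.5 * (|k+1|^2H - 2|k|^2H + |k-1|^2H)``."""
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H)
                  + np.abs(k - 1) ** (2 * H))


def fgn(H: float, size: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Exact unit-variance fractional Gaussian noise.

    Draws from the closed-form Toeplitz covariance via its Cholesky factor,
    so the sample autocovariance is exact in expectation at every lag.
    O(N^3) in the series length, which is ample for the frame counts used
    here (hundreds).
    """
    from scipy.linalg import cholesky, toeplitz

    m, N = size
    if N == 1:
        return rng.standard_normal((m, 1))
    gamma = fgn_autocovariance(H, np.arange(N))
    L = cholesky(toeplitz(gamma), lower=True)
    return rng.standard_normal((m, N)) @ L.T


def simulate_fbm(alpha: float, T: int, n: int, seed: int) -> LabeledTrajectoryDataset:
    """Fractional Brownian motion with Hurst exponent H = alpha/2.

    Increments per component are exact fractional Gaussian noise,
    independent across components; MSD scales as t^alpha.
    """
    _check_T_n(T, n)
    if not 0 < alpha < 2:
        raise ValueError("FBM requires alpha in (0, 2)")
    H = alpha / 2.0
    rng = np.random.default_rng(seed)
    steps = fgn(H, (2 * n, T - 1), rng).reshape(n, 2, T - 1)
    pos = np.concatenate([np.zeros((n, 2, 1)), np.cumsum(steps, axis=-1)], axis=-1)
    return _dataset(pos, "FBM")


# ---------------------------------------------------------------------------
# power-law sampling shared by CTRW / LW
# ---------------------------------------------------------------------------

def pareto_times(tail, size, rng: np.random.Generator) -> np.ndarray:
    """Continuous Pareto draws with survival exponent ``tail`` and minimum 1.

    ``tail`` may be a scalar or an array broadcastable to ``size``.
    """
    u = rng.random(size)
    return u ** (-1.0 / np.asarray(tail, dtype=float))


# ---------------------------------------------------------------------------
# continuous-time random walk
# ---------------------------------------------------------------------------

def simulate_ctrw(alpha: float, T: int, n: int, seed: int) -> LabeledTrajectoryDataset:
    """CTRW: power-law waits psi(tau) ~ tau^-(1+alpha) between Gaussian jumps.

    Positions are regularized onto the uniform frame grid with a zero-order
    hold: the particle sits at its last renewal position between jumps.
    """
    _check_T_n(T, n)
    if not 0 < alpha <= 1:
        raise ValueError("CTRW requires alpha in (0, 1]")
    rng = np.random.default_rng(seed)
    # waits have minimum 1 frame, so at most T renewals fall inside the window
    waits = pareto_times(alpha, (n, T), rng)
    renewal_times = np.cumsum(waits, axis=1)
    jumps = rng.standard_normal((n, T, 2))
    walk = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(jumps, axis=1)], axis=1)
    frames = np.arange(T, dtype=float)
    pos = np.zeros((n, 2, T))
    for i in range(n):
        k = np.searchsorted(renewal_times[i], frames, side="right")
        pos[i] = walk[i, k].T  # zero-order hold between renewals
    return _dataset(pos, "CTRW")


# ---------------------------------------------------------------------------
# Lévy walk
# ---------------------------------------------------------------------------

def simulate_lw(alpha: float, T: int, n: int, seed: int,
                v_scale: float = 1.0) -> LabeledTrajectoryDataset:
    """Lévy walk: constant-velocity flights with power-law durations.

    Flight durations follow phi(tau) ~ tau^-(4-alpha) (survival exponent
    sigma = 3 - alpha; at alpha = 2, sigma is drawn uniformly from (0, 3)
    per flight).  Each flight has one heading theta ~ U[0, 2pi) and one
    speed v drawn from a half-normal with scale ``v_scale``; within the
    flight every per-frame step is (v cos theta, v sin theta).
    """
    _check_T_n(T, n)
    if not 1 <= alpha <= 2:
        raise ValueError("LW requires alpha in [1, 2]")
    rng = np.random.default_rng(seed)
    n_steps = T - 1
    pos = np.zeros((n, 2, T))
    for i in range(n):
        # at most n_steps flights of minimum duration 1 are ever needed
        if alpha == 2:
            sigma = rng.uniform(0.0, 3.0, size=n_steps)
        else:
            sigma = 3.0 - alpha
        durs = np.ceil(np.minimum(pareto_times(sigma, n_steps, rng),
                                  n_steps)).astype(int)  # window-truncated
        theta = rng.uniform(0, 2 * np.pi, size=n_steps)
        v = np.abs(rng.standard_normal(n_steps)) * v_scale
        vx = np.repeat(v * np.cos(theta), durs)[:n_steps]
        vy = np.repeat(v * np.sin(theta), durs)[:n_steps]
        pos[i, 0, 1:] = np.cumsum(vx)
        pos[i, 1, 1:] = np.cumsum(vy)
    return _dataset(pos, "LW")


# ---------------------------------------------------------------------------
# annealed transient time motion
# ---------------------------------------------------------------------------

def simulate_attm(alpha: float, T: int, n: int, seed: int,
                  gamma: float = 1.5,
                  fixed_D: float | None = None) -> LabeledTrajectoryDataset:
    """ATTM: piecewise Brownian segments with a fluctuating diffusivity.

    Each segment draws D_i from P(D) ~ D^(sigma/gamma - 1) on (0, 1] with
    sigma = alpha * gamma and lasts t_i = D_i^-gamma frames (rounded up,
    >= 1).  Within a segment the walk is Brownian with diffusivity D_i:
    every frame takes an independent Gaussian step whose variance is
    2 D_i t_i split evenly over the segment's frames, so the per-segment
    displacement variance is exactly 2 D_i t_i per component while the
    frame-resolved motion stays diffusive (no ballistic runs).

    ``fixed_D`` collapses the diffusivity distribution to a point mass —
    the degenerate limit in which every segment becomes a plain Gaussian
    step of variance 2 D t per component (useful for validation).
    """
    _check_T_n(T, n)
    if not 0 < alpha < 1:
        raise ValueError("ATTM requires alpha in (0, 1)")
    sigma = alpha * gamma
    rng = np.random.default_rng(seed)
    n_steps = T - 1
    pos = np.zeros((n, 2, T))
    for i in range(n):
        if fixed_D is not None:
            D = np.full(n_steps, float(fixed_D))
        else:
            # inverse-CDF draw from P(D) ~ D^(sigma/gamma - 1) on (0, 1]
            D = rng.random(n_steps) ** (gamma / sigma)
        dur_f = np.minimum(D ** (-gamma), n_steps)  # window-truncated
        durs = np.ceil(dur_f).astype(int)  # >= 1 frame per segment
        # per-frame Gaussian steps with variance (2 D t_i) / n_frames
        step_sd = np.repeat(np.sqrt(2 * D * dur_f / durs), durs)[:n_steps]
        steps = step_sd[None, :] * rng.standard_normal((2, n_steps))
        pos[i, :, 1:] = np.cumsum(steps, axis=1)
    return _dataset(pos, "ATTM")


# ---------------------------------------------------------------------------
# scaled Brownian motion
# ---------------------------------------------------------------------------

def simulate_sbm(alpha: float, T: int, n: int, seed: int,
                 sigma_sq: float = 1.0) -> LabeledTrajectoryDataset:
    """SBM: Gaussian steps whose variance follows the exact scaling law.

    Step i has per-component variance sigma_sq * ((i+1)^alpha - i^alpha),
    so the cumulative variance at frame k is exactly sigma_sq * k^alpha.
    """
    _check_T_n(T, n)
    if not 0 < alpha <= 2:
        raise ValueError("SBM requires alpha in (0, 2]")
    rng = np.random.default_rng(seed)
    i = np.arange(T - 1, dtype=float)
    step_var = sigma_sq * ((i + 1) ** alpha - i ** alpha)
    steps = rng.standard_normal((n, 2, T - 1)) * np.sqrt(step_var)[None, None, :]
    pos = np.concatenate([np.zeros((n, 2, 1)), np.cumsum(steps, axis=-1)], axis=-1)
    return _dataset(pos, "SBM")


# ---------------------------------------------------------------------------
# balanced benchmark builder
# ---------------------------------------------------------------------------

_SIMULATORS = {
    "BM": lambda a, T, n, s: simulate_bm(T, n, s),
    "FBM": simulate_fbm,
    "CTRW": simulate_ctrw,
    "LW": simulate_lw,
    "ATTM": simulate_attm,
    "SBM": simulate_sbm,
}


def make_labeled_dataset(classes: tuple[str, ...] = SIMULATED_CLASSES,
                         n_per_class: int = 1000, T: int = 200, *, seed: int,
                         alpha_ranges: dict[str, tuple[float, float]] | None = None,
                         ) -> LabeledTrajectoryDataset:
    """Build a balanced, normalized multi-class benchmark dataset.

    Every trajectory draws its own anomalous exponent uniformly from its
    class range (:data:`CLASS_ALPHA_RANGES` by default) and is normalized
    to start at the origin with pooled displacement SD 1.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ranges = dict(CLASS_ALPHA_RANGES)
    if alpha_ranges:
        ranges.update(alpha_ranges)
    ss = np.random.SeedSequence(seed)
    trajs: list[Trajectory] = []
    labels: list[str] = []
    for cls, child in zip(classes, ss.spawn(len(classes))):
        if cls not in _SIMULATORS:
            raise ValueError(f"unknown diffusion class {cls!r}")
        lo, hi = ranges[cls]
        rng = np.random.default_rng(child)
        seeds = rng.integers(0, 2 ** 31 - 1, size=n_per_class)
        alphas = rng.uniform(lo, hi, size=n_per_class)
        for a, s in zip(alphas, seeds):
            # ATTM requires alpha strictly inside (0, 1)
            if cls == "ATTM":
                a = min(max(a, 0.1), 0.99)
            # a draw can be constant inside the window (e.g. a CTRW with no
            # renewal before frame T at small alpha); redraw until it is
            # normalizable
            while True:
                ds = _SIMULATORS[cls](float(a), T, 1, int(s))
                traj = ds.trajectories[0]
                try:
                    norm, _ = normalize_trajectory(traj)
                    break
                except DegenerateTrajectoryError:
                    s = int(rng.integers(0, 2 ** 31 - 1))
            norm.meta["alpha"] = float(a)
            trajs.append(norm)
            labels.append(cls)
    return LabeledTrajectoryDataset(trajs, labels)
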