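"""Trajectory data model, normalization, segmentation and dataset I/O.

A :class:`Trajectory` is a uniformly sampled 2-D position series
``r(t) = (x(t), y(t))`` as extracted from a liquid-phase TEM movie (or a
simulator).  Datasets of equal-length trajectories carry one diffusion-class
label per trajectory and round-trip losslessly through HDF5 or long-format
CSV.

The module also ships :func:`generate_surrogate_lptem`, a seeded two-state
(dwell/jump) process that emulates the phenomenology of nanoparticles
moving near the membrane window of a liquid cell: long confined dwells with
anticorrelated steps, interrupted by rare heavy-tailed escape jumps.  It
makes the whole pipeline testable without any experimental download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Trajectory", "NormalizationRecord", "LabeledTrajectoryDataset",
    "DegenerateTrajectoryError", "normalize_trajectory", "denormalize_trajectory",
    "segment_trajectory", "save_dataset", "load_dataset",
    "generate_surrogate_lptem", "SURROGATE_LABEL",
]

SURROGATE_LABEL = "LPTEM"


class DegenerateTrajectoryError(ValueError):
    """Raised when an operation requires non-zero displacement variance."""


@dataclass(frozen=True)
class Trajectory:
    """A 2-D single-particle trajectory sampled at a uniform frame interval.

    Parameters
    ----------
    xs, ys:
        Position series of equal length ``T >= 2`` in arbitrary (but
        consistent) length units.
    frame_interval:
        Seconds per frame; defaults to 1 frame unit.
    meta:
        Optional acquisition tags, e.g. ``dose_rate`` (e-/A^2 s),
        ``particle_length`` (nm), ``source_id``.
    """

    xs: np.ndarray
    ys: np.ndarray
    frame_interval: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        xs = np.asarray(self.xs, dtype=np.float64)
        ys = np.asarray(self.ys, dtype=np.float64)
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)
        if xs.ndim != 1 or ys.ndim != 1 or len(xs) != len(ys):
            raise ValueError("xs and ys must be 1-D arrays of equal length")
        if len(xs) < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
            raise ValueError("trajectory positions must be finite")

    def __len__(self) -> int:
        return len(self.xs)

    @property
    def positions(self) -> np.ndarray:
        """(T, 2) array of positions."""
        return np.column_stack([self.xs, self.ys])


@dataclass(frozen=True)
class NormalizationRecord:
    """Affine record (origin shift, isotropic scale) inverting a normalization."""

    origin: tuple[float, float]
    scale: float

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be positive")


@dataclass
class LabeledTrajectoryDataset:
    """Equal-length trajectories with one diffusion-class label each."""

    trajectories: list[Trajectory]
    labels: list[str]
    split: str | None = None

    def __post_init__(self):
        if len(self.trajectories) != len(self.labels):
            raise ValueError("need exactly one label per trajectory")
        lengths = {len(t) for t in self.trajectories}
        if len(lengths) > 1:
            raise ValueError(f"trajectories have mixed lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def T(self) -> int:
        if not self.trajectories:
            return 0
        return len(self.trajectories[0])

    def positions(self) -> np.ndarray:
        """(n, 2, T) stacked position array."""
        return np.stack([[t.xs, t.ys] for t in self.trajectories])

    def subset(self, indices: Sequence[int]) -> "LabeledTrajectoryDataset":
        return LabeledTrajectoryDataset(
            [self.trajectories[i] for i in indices],
            [self.labels[i] for i in indices], split=self.split)


def _pooled_step_sd(traj: Trajectory) -> float:
    steps = np.concatenate([np.diff(traj.xs), np.diff(traj.ys)])
    return float(np.std(steps))  # population SD of the pooled components


def normalize_trajectory(traj: Trajectory) -> tuple[Trajectory, NormalizationRecord]:
    """Shift a trajectory to start at the origin and rescale its steps.

    Both components are divided by the pooled (x and y concatenated)
    population standard deviation of the lag-1 displacements, so the
    returned trajectory starts at (0, 0) and has pooled displacement SD
    exactly 1.  This makes absolute length units
    immaterial to every downstream statistic and model.

    Raises
    ------
    DegenerateTrajectoryError
        If the trajectory is constant in both components.
    """
    scale = _pooled_step_sd(traj)
    if scale == 0.0:
        raise DegenerateTrajectoryError(
            "constant trajectory has zero displacement SD and cannot be normalized")
    origin = (float(traj.xs[0]), float(traj.ys[0]))
    out = Trajectory((traj.xs - origin[0]) / scale, (traj.ys - origin[1]) / scale,
                     frame_interval=traj.frame_interval, meta=dict(traj.meta))
    return out, NormalizationRecord(origin=origin, scale=scale)


def denormalize_trajectory(traj: Trajectory, record: NormalizationRecord) -> Trajectory:
    """Exactly invert :func:`normalize_trajectory`."""
    return Trajectory(traj.xs * record.scale + record.origin[0],
                      traj.ys * record.scale + record.origin[1],
                      frame_interval=traj.frame_interval, meta=dict(traj.meta))


def segment_trajectory(traj: Trajectory, segment_length: int) -> list[Trajectory]:
    """Cut a trajectory into consecutive non-overlapping fixed-length pieces.

    The trailing remainder shorter than ``segment_length`` is dropped; a
    trajectory shorter than one segment yields an empty list.  Metadata and
    the frame interval propagate to every segment.
    """
    if segment_length < 2:
        raise ValueError("segment_length must be >= 2")
    n_seg = len(traj) // segment_length
    out = []
    for i in range(n_seg):
        sl = slice(i * segment_length, (i + 1) * segment_length)
        meta = dict(traj.meta)
        meta["segment_index"] = i
        out.append(Trajectory(traj.xs[sl].copy(), traj.ys[sl].copy(),
                              frame_interval=traj.frame_interval, meta=meta))
    return out


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("dose_rate", "particle_length")


def save_dataset(ds: LabeledTrajectoryDataset, path, format: str = "hdf5") -> None:
    """Write a dataset to ``path`` as HDF5 (``/x``, ``/y``, ``/label``) or
    long-format CSV (``traj_id, frame, x, y, label``)."""
    path = Path(path)
    if format == "hdf5":
        _save_hdf5(ds, path)
    elif format == "csv":
        _save_csv(ds, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _save_hdf5(ds: LabeledTrajectoryDataset, path: Path) -> None:
    n, T = len(ds), ds.T
    with h5py.File(path, "w") as f:
        x = np.zeros((n, T))
        y = np.zeros((n, T))
        for i, t in enumerate(ds.trajectories):
            x[i], y[i] = t.xs, t.ys
        f.create_dataset("x", data=x)
        f.create_dataset("y", data=y)
        f.create_dataset("label", data=np.array(ds.labels, dtype="S"))
        f.attrs["frame_interval"] = (
            ds.trajectories[0].frame_interval if ds.trajectories else 1.0)
        if ds.split is not None:
            f.attrs["split"] = ds.split
        for key in _META_KEYS:
            vals = np.array([float(t.meta.get(key, np.nan))
                             for t in ds.trajectories])
            if n and np.isfinite(vals).any():
                f.create_dataset(key, data=vals)
        sources = [str(t.meta.get("source_id", "")) for t in ds.trajectories]
        if any(sources):
            f.create_dataset("source_id", data=np.array(sources, dtype="S"))


def _save_csv(ds: LabeledTrajectoryDataset, path: Path) -> None:
    rows = []
    for i, (t, label) in enumerate(zip(ds.trajectories, ds.labels)):
        frame = np.arange(len(t))
        df = pd.DataFrame({"traj_id": i, "frame": frame,
                           "x": t.xs, "y": t.ys, "label": label})
        for key in _META_KEYS:
            if key in t.meta:
                df[key] = t.meta[key]
        rows.append(df)
    out = (pd.concat(rows, ignore_index=True) if rows else
           pd.DataFrame(columns=["traj_id", "frame", "x", "y", "label"]))
    out.to_csv(path, index=False, float_format="%.17g")


def load_dataset(path) -> LabeledTrajectoryDataset:
    """Load a dataset written by :func:`save_dataset` (format auto-detected)."""
    path = Path(path)
    if h5py.is_hdf5(path):
        return _load_hdf5(path)
    return _load_csv(path)


def _load_hdf5(path: Path) -> LabeledTrajectoryDataset:
    with h5py.File(path, "r") as f:
        x = np.asarray(f["x"])
        y = np.asarray(f["y"])
        labels = [s.decode() for s in f["label"][()]] if len(x) else []
        frame_interval = float(f.attrs.get("frame_interval", 1.0))
        split = f.attrs.get("split")
        metas: list[dict] = [{} for _ in range(len(x))]
        for key in _META_KEYS:
            if key in f:
                vals = np.asarray(f[key])
                for i, v in enumerate(vals):
                    if np.isfinite(v):
                        metas[i][key] = float(v)
        if "source_id" in f:
            for i, s in enumerate(f["source_id"][()]):
                if s:
                    metas[i]["source_id"] = s.decode()
    trajs = [Trajectory(x[i], y[i], frame_interval=frame_interval, meta=metas[i])
             for i in range(len(x))]
    return LabeledTrajectoryDataset(trajs, labels,
                                    split=str(split) if split is not None else None)


def _load_csv(path: Path) -> LabeledTrajectoryDataset:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed file
        raise ValueError(f"could not parse {path} as a trajectory CSV") from exc
    required = {"traj_id", "frame", "x", "y", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV is missing columns {sorted(required - set(df.columns))}")
    trajs, labels = [], []
    for tid, g in df.groupby("traj_id", sort=True):
        g = g.sort_values("frame")
        meta = {k: float(g[k].iloc[0]) for k in _META_KEYS if k in g.columns}
        trajs.append(Trajectory(g["x"].to_numpy(), g["y"].to_numpy(), meta=meta))
        labels.append(str(g["label"].iloc[0]))
    return LabeledTrajectoryDataset(trajs, labels)


# ---------------------------------------------------------------------------
# surrogate LPTEM generator
# ---------------------------------------------------------------------------

def generate_surrogate_lptem(n: int, T: int, *, seed: int,
                             spring_k: float = 0.8,
                             dwell_noise: float = 1.0,
                             jump_prob: float = 0.03,
                             jump_scale: float = 10.0,
                             jump_tail: float = 6.0,
                             mix: tuple[float, float] = (1.0, 1.0)) -> LabeledTrajectoryDataset:
    """Generate surrogate liquid-cell trajectories (label ``LPTEM``).

    Each trajectory alternates between (i) confined dwell phases — an
    over-damped spring pulls the particle back toward the current trap
    centre, producing small anticorrelated steps (lag-1 velocity
    autocorrelation ~ ``-spring_k / 2``) — and (ii) rare escape jumps whose
    amplitude is Pareto distributed with tail index ``jump_tail``, which
    relocate the trap centre and give the displacement distribution its
    heavy non-Gaussian tails.

    Parameters
    ----------
    n, T:
        Number of trajectories and frames per trajectory.
    seed:
        Seeds all randomness; identical seeds give identical datasets.
    spring_k:
        Trap stiffness in (0, 2); larger values give stronger anticorrelation.
    dwell_noise:
        SD of the thermal kick inside a trap (arbitrary length units).
    jump_prob:
        Per-frame probability of an escape jump; 0 disables jumps.
    jump_scale, jump_tail:
        Scale and Pareto tail index of the jump amplitude.
    mix:
        Relative weights of the (dwell, jump-enabled) regimes used to assign
        per-trajectory regimes; must be nonnegative with positive sum.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if T < 2:
        raise ValueError("T must be >= 2")
    w = np.asarray(mix, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("mix weights must be nonnegative with positive sum")
    if not 0 < spring_k < 2:
        raise ValueError("spring_k must lie in (0, 2)")
    rng = np.random.default_rng(seed)

    p_jump_regime = w[1] / w.sum()
    jump_on = rng.random(n) < p_jump_regime

    pos = np.zeros((n, 2, T))
    centre = np.zeros((n, 2))
    x = np.zeros((n, 2))
    for t in range(1, T):
        kick = rng.standard_normal((n, 2)) * dwell_noise
        x = x - spring_k * (x - centre) + kick
        jumps = (rng.random(n) < jump_prob) & jump_on
        if jumps.any():
            k = int(jumps.sum())
            amp = jump_scale * (rng.pareto(jump_tail, size=k) + 1.0)
            theta = rng.uniform(0, 2 * np.pi, size=k)
            dv = amp[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
            x[jumps] += dv
            centre[jumps] = x[jumps]
        pos[:, :, t] = x
    trajs = [Trajectory(pos[i, 0], pos[i, 1],
                        meta={"source_id": f"surrogate-{seed}-{i}"})
             for i in range(n)]
    return LabeledTrajectoryDataset(trajs, [SURROGATE_LABEL] * n)
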