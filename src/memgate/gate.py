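"""Gate-opening quantification.

The cavity gate is described by two diagnostic inter-residue distances:
d1 between the loop-1 tryptophan (W473 analogue) and the loop-4
proline (P564 analogue), and d2 between the loop-1 serine (S476) and
the loop-4 tryptophan (W562). Closed and open states separate cleanly
in these coordinates, so the module provides a Gaussian kernel density
estimate of the state distribution and a threshold-based open/closed
segmentation with a minimum-dwell merge rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .core import FrameWindow, Trajectory, TopologyError
from .geometry import cross_distances

__all__ = [
    "GateDistanceSeries",
    "StateDensity",
    "StateInterval",
    "gate_distances",
    "estimate_state_density",
    "segment_states",
]

MIN_KDE_SAMPLES = 50


@dataclass
class GateDistanceSeries:
    d1: np.ndarray               # per-frame Å, pair1
    d2: np.ndarray               # per-frame Å, pair2
    pair1: tuple                 # residue keys
    pair2: tuple
    mode: str                    # atom-choice mode used
    times: np.ndarray


@dataclass
class StateDensity:
    grid: np.ndarray             # (n,) for 1D; (2, ny, nx) mesh for 2D
    density: np.ndarray
    bandwidth: float             # KDE scale factor actually used
    integral: float
    coordinate: str

    def modes(self, min_prominence: float = 0.0) -> np.ndarray:
        """Local maxima of a 1D density, largest first."""
        d = self.density
        if d.ndim != 1:
            raise ValueError("modes() applies to 1D densities")
        interior = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
        idx = np.nonzero(interior)[0] + 1
        if min_prominence > 0:
            idx = idx[d[idx] >= min_prominence * d.max()]
        order = np.argsort(d[idx])[::-1]
        return self.grid[idx[order]]


@dataclass(frozen=True)
class StateInterval:
    state: str                   # "open" / "closed"
    window: FrameWindow


def _residue_atoms(traj: Trajectory, resid: int, segid=None) -> list:
    ids = [a.atom_id for a in traj.topology
           if a.residue_id == resid
           and (segid is None or a.segment_id == segid)]
    if not ids:
        raise TopologyError(f"no residue {resid} in topology")
    return ids


def gate_distances(traj: Trajectory, pair1: tuple, pair2: tuple,
                   mode: str = "closest-heavy-atom",
                   segid=None, named_atom: str = "CA"
                   ) -> GateDistanceSeries:
    """Per-frame d1/d2 for two residue pairs given as residue ids.

    ``mode``: ``closest-heavy-atom`` (default; robust to side-chain
    flips of the gate tryptophans), ``Ca-Ca``, or ``named-atom`` with
    ``named_atom``.
    """
    if mode not in ("closest-heavy-atom", "Ca-Ca", "named-atom"):
        raise ValueError(f"unknown mode {mode!r}")

    def atoms_for(resid):
        ids = _residue_atoms(traj, resid, segid)
        if mode == "closest-heavy-atom":
            ids = [i for i in ids if traj.topology[i].element != "H"]
        else:
            name = "CA" if mode == "Ca-Ca" else named_atom
            ids = [i for i in ids if traj.topology[i].name == name]
        if not ids:
            raise TopologyError(
                f"residue {resid} has no atoms for mode {mode!r}")
        return ids

    groups = [atoms_for(r) for pair in (pair1, pair2) for r in pair]
    d1 = np.empty(traj.n_frames)
    d2 = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        d1[k] = cross_distances(fr.coords, groups[0], groups[1],
                                fr.box).min()
        d2[k] = cross_distances(fr.coords, groups[2], groups[3],
                                fr.box).min()

    def key(resid):
        a = traj.topology[_residue_atoms(traj, resid, segid)[0]]
        return a.residue_key

    return GateDistanceSeries(
        d1=d1, d2=d2, pair1=(key(pair1[0]), key(pair1[1])),
        pair2=(key(pair2[0]), key(pair2[1])), mode=mode,
        times=traj.times)


def estimate_state_density(samples, bandwidth=None, grid_points: int = 512,
                           coordinate: str = "distance") -> StateDensity:
    """Gaussian KDE of a distance coordinate (1D) or of (d1, d2) (2D).

    Bandwidth follows Scott's rule unless a scalar factor is given.
    The density is evaluated on a regular grid padded by three
    bandwidths and renormalized so the grid quadrature integrates to 1.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[None, :]
    n = samples.shape[1]
    if n < MIN_KDE_SAMPLES:
        raise ValueError(
            f"need at least {MIN_KDE_SAMPLES} samples for a state "
            f"density, got {n}; analyse more frames")
    kde = gaussian_kde(samples, bw_method=bandwidth)
    if samples.shape[0] == 1:
        sd = samples.std(ddof=1)
        h = kde.factor * (sd if sd > 0 else 1.0)
        lo, hi = samples.min() - 3 * h, samples.max() + 3 * h
        grid = np.linspace(lo, hi, grid_points)
        density = kde(grid[None, :])
        integral = float(np.trapezoid(density, grid))
        density = density / integral
        return StateDensity(grid=grid, density=density,
                            bandwidth=float(kde.factor),
                            integral=float(np.trapezoid(density, grid)),
                            coordinate=coordinate)
    if samples.shape[0] != 2:
        raise ValueError("samples must be 1D or 2D")
    h = kde.factor * samples.std(axis=1, ddof=1)
    lo = samples.min(axis=1) - 3 * h
    hi = samples.max(axis=1) + 3 * h
    gx = np.linspace(lo[0], hi[0], grid_points)
    gy = np.linspace(lo[1], hi[1], grid_points)
    mx, my = np.meshgrid(gx, gy)
    density = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(mx.shape)
    integral = float(np.trapezoid(np.trapezoid(density, gx, axis=1), gy))
    density = density / integral
    new_int = float(np.trapezoid(np.trapezoid(density, gx, axis=1), gy))
    return StateDensity(grid=np.stack([mx, my]), density=density,
                        bandwidth=float(kde.factor), integral=new_int,
                        coordinate=coordinate)


def segment_states(series: np.ndarray, open_threshold: float,
                   min_dwell: float = 0.0,
                   frame_interval: float = 1.0) -> list:
    """Two-state open/closed segmentation of a gate-distance series.

    Frames with distance > ``open_threshold`` are open. Intervals
    shorter than ``min_dwell`` (ns) are absorbed into their neighbours
    (shortest first; ties resolved leftmost), so brief spikes do not
    fragment the segmentation. The returned intervals tile the
    trajectory exactly.
    """
    if open_threshold <= 0:
        raise ValueError("open_threshold must be positive")
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n == 0:
        return []
    is_open = series > open_threshold
    intervals = []
    start = 0
    for k in range(1, n + 1):
        if k == n or is_open[k] != is_open[start]:
            intervals.append([("open" if is_open[start] else "closed"),
                              start, k - 1])
            start = k
    min_frames = int(np.ceil(min_dwell / frame_interval - 1e-9)) \
        if min_dwell > 0 else 0
    while len(intervals) > 1:
        lengths = [iv[2] - iv[1] + 1 for iv in intervals]
        shortest = min(range(len(intervals)), key=lambda i: (lengths[i], i))
        if lengths[shortest] >= min_frames:
            break
        st, lo, hi = intervals.pop(shortest)
        if shortest > 0:
            intervals[shortest - 1][2] = hi
            if shortest < len(intervals) \
                    and intervals[shortest][0] == \
                    intervals[shortest - 1][0]:
                nxt = intervals.pop(shortest)
                intervals[shortest - 1][2] = nxt[2]
        else:
            intervals[0][1] = lo
    return [StateInterval(state=st, window=FrameWindow(lo, hi))
            for st, lo, hi in intervals]


def open_fraction(intervals, n_frames: int | None = None) -> float:
    """Fraction of frames labelled open by :func:`segment_states`."""
    if not intervals:
        return 0.0
    total = sum(len(iv.window) for iv in intervals)
    open_frames = sum(len(iv.window) for iv in intervals
                      if iv.state == "open")
    return open_frames / (n_frames or total)


def intervals_table(intervals, frame_interval: float = 1.0) -> pd.DataFrame:
    rows = [{"state": iv.window and iv.state,
             "start_frame": iv.window.start_frame,
             "end_frame": iv.window.end_frame,
             "duration_ns": len(iv.window) * frame_interval}
            for iv in intervals]
    return pd.DataFrame(rows)
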