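"""Membrane-referenced protein descriptors.

Everything here is referenced to the phosphorus plane of the
protein-proximal leaflet: binding-event detection (sustained minimum
heavy-atom contact), per-residue insertion depth (Cb, or Ca for
glycine, relative to the averaged plane), the helix tilt-angle series,
weighted density profiles along the membrane normal, and minimum
protein-bilayer distance series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FrameWindow, Trajectory, TopologyError, is_protein_atom
from .geometry import (BilayerReference, assign_leaflets, cross_distances,
                       fit_phosphorus_plane, vector_angle_to_z)
from .core import ATOMIC_NUMBERS

__all__ = [
    "DepthProfile",
    "DensityProfile",
    "detect_binding_event",
    "proximal_leaflet_reference",
    "depth_of_insertion",
    "tilt_series",
    "density_profile",
    "min_distance_series",
]


@dataclass
class DepthProfile:
    """Per-residue insertion depth over the bound window.

    Depth is signed: positive above the phosphorus plane (solvent
    side), negative below it (inserted past the phosphates).
    """

    table: pd.DataFrame          # residue_key, resid, resname, mean, sd
    window: FrameWindow
    plane_mode: str              # "window-average" or "per-frame"


@dataclass
class DensityProfile:
    bin_edges: np.ndarray
    counts: dict                 # group -> summed weighted counts per bin
    density: dict                # group -> weight per cubic Å (frame mean)
    weighting: str
    n_frames: int


def min_distance_series(traj: Trajectory, group_a, group_b) -> np.ndarray:
    """Per-frame minimum cross distance (x/y minimum image), heavy or
    otherwise as selected by the caller."""
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be nonempty")
    out = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        out[k] = cross_distances(fr.coords, group_a, group_b, fr.box).min()
    return out


def detect_binding_event(traj: Trajectory, protein_ids, bilayer_ids,
                         cutoff: float = 4.0, dwell: float = 10.0):
    """First frame from which the minimum protein-bilayer heavy-atom
    distance stays <= ``cutoff`` (Å) for at least ``dwell`` (ns)
    continuously; ``None`` if never satisfied.

    The run may continue to the trajectory end; only its first
    ``dwell`` worth of frames must be uninterrupted.
    """
    if dwell < traj.frame_interval - 1e-9:
        raise ValueError(
            f"dwell ({dwell} ns) shorter than the frame interval "
            f"({traj.frame_interval} ns)")
    heavy = {a.atom_id for a in traj.topology if a.element != "H"}
    ga = [i for i in protein_ids if i in heavy]
    gb = [i for i in bilayer_ids if i in heavy]
    dmin = min_distance_series(traj, ga, gb)
    n_dwell = int(np.ceil(dwell / traj.frame_interval - 1e-9))
    below = dmin <= cutoff
    run = 0
    for k, ok in enumerate(below):
        run = run + 1 if ok else 0
        if run >= n_dwell:
            return k - n_dwell + 1
    return None


def proximal_leaflet_reference(traj: Trajectory, protein_ids,
                               bound_window: FrameWindow
                               ) -> BilayerReference:
    """Phosphorus-plane reference of the leaflet engaged by the protein.

    The proximal leaflet is the one whose averaged phosphorus plane is
    nearer the protein centroid at the window start (the binding
    frame); the assignment is fixed for the run.
    """
    leaflets = assign_leaflets(traj, frame_index=0)
    f0 = bound_window.start_frame
    prot_z = traj.frames[f0].coords[list(protein_ids), 2].mean()
    dist = {}
    for name, ids in leaflets.items():
        if ids:
            dist[name] = abs(traj.frames[f0].coords[ids, 2].mean() - prot_z)
    proximal = min(dist, key=dist.get)
    ref = fit_phosphorus_plane(traj, leaflets[proximal], bound_window)
    ref.leaflet_ids = {**leaflets, "proximal": leaflets[proximal],
                       "proximal_name": proximal}
    ref.leaflet_planes = {}
    for name, ids in leaflets.items():
        if ids:
            other = fit_phosphorus_plane(traj, ids, bound_window)
            ref.leaflet_planes[name] = other.averaged_z
    return ref


def depth_of_insertion(traj: Trajectory, ref: BilayerReference,
                       bound_window: FrameWindow,
                       protein_ids=None,
                       plane_mode: str = "window-average") -> DepthProfile:
    """Signed depth of each residue's Cb (Ca for glycine) relative to
    the phosphorus plane, averaged over the bound window.

    ``plane_mode='window-average'`` references the time-averaged plane;
    ``'per-frame'`` references each frame's own plane.
    """
    if plane_mode not in ("window-average", "per-frame"):
        raise ValueError(f"unknown plane_mode {plane_mode!r}")
    bound_window = bound_window.clipped(traj.n_frames)
    if protein_ids is None:
        protein_ids = [a.atom_id for a in traj.topology
                       if is_protein_atom(a)]
    protein_ids = set(protein_ids)
    residues: dict = {}
    for a in traj.topology:
        if a.atom_id in protein_ids:
            residues.setdefault((a.segment_id, a.residue_id), []).append(a)
    rows = []
    fsl = slice(bound_window.start_frame, bound_window.end_frame + 1)
    coords = traj.coords[fsl]
    if plane_mode == "window-average":
        plane = ref.averaged_z
    else:
        plane = ref.plane_z[fsl]
    for (seg, rid), atoms in sorted(residues.items()):
        by_name = {a.name: a for a in atoms}
        anchor = by_name.get("CB") or by_name.get("CA")
        if anchor is None:
            raise TopologyError(
                f"residue {seg}/{rid} has neither CB nor CA")
        z = coords[:, anchor.atom_id, 2]
        depth = z - plane
        rows.append({
            "residue_key": anchor.residue_key, "resid": rid,
            "resname": anchor.residue_name, "anchor": anchor.name,
            "depth_mean": float(np.mean(depth)),
            "depth_sd": float(np.std(depth, ddof=0)),
        })
    return DepthProfile(pd.DataFrame(rows), bound_window, plane_mode)


def tilt_series(traj: Trajectory, atom_a: int, atom_b: int,
                bound_window: FrameWindow | None = None):
    """Per-frame folded helix tilt (deg, [0, 90]) of the a->b axis
    against the membrane normal; returns (series, mean, sd) with the
    summary over the bound window (whole trajectory if not given)."""
    series = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        v = fr.coords[atom_b] - fr.coords[atom_a]
        series[k] = vector_angle_to_z(v, fold=True)
    if bound_window is None:
        bound_window = FrameWindow(0, traj.n_frames - 1)
    bound_window = bound_window.clipped(traj.n_frames)
    sl = series[bound_window.start_frame:bound_window.end_frame + 1]
    return series, float(np.mean(sl)), float(np.std(sl, ddof=0))


def density_profile(traj: Trajectory, groups: dict, window: FrameWindow,
                    bin_width: float = 1.0, weighting: str = "electron",
                    z_range: tuple | None = None) -> DensityProfile:
    """Weighted number-density profile along z, averaged over the window.

    ``weighting``: ``electron`` (atomic number), ``mass`` (Da) or
    ``number`` (unit weights). ``counts`` holds raw weighted histogram
    counts summed over frames (their total equals sum-of-weights times
    n_frames when the range covers all atoms); ``density`` divides by
    n_frames and the bin volume (box cross-section times bin width).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if weighting not in ("electron", "mass", "number"):
        raise ValueError(f"unknown weighting {weighting!r}")
    window = window.clipped(traj.n_frames)
    frames = traj.frames[window.start_frame:window.end_frame + 1]
    if z_range is None:
        zmax = max(abs(fr.coords[:, 2]).max() for fr in frames) + bin_width
        half = np.ceil(zmax / bin_width) * bin_width
        z_range = (-half, half)
    n_bins = int(round((z_range[1] - z_range[0]) / bin_width))
    edges = z_range[0] + bin_width * np.arange(n_bins + 1)

    def weight(atom):
        if weighting == "number":
            return 1.0
        if weighting == "mass":
            return atom.mass
        return float(ATOMIC_NUMBERS.get(atom.element, 0))

    area = np.mean([fr.box[0] * fr.box[1] for fr in frames])
    counts, density = {}, {}
    for name, ids in groups.items():
        ids = list(ids)
        if not ids:
            counts[name] = np.zeros(n_bins)
            density[name] = np.zeros(n_bins)
            continue
        w = np.array([weight(traj.topology[i]) for i in ids])
        hist = np.zeros(n_bins)
        for fr in frames:
            h, _ = np.histogram(fr.coords[ids, 2], bins=edges, weights=w)
            hist += h
        counts[name] = hist
        density[name] = hist / (len(frames) * area * bin_width)
    return DensityProfile(bin_edges=edges, counts=counts, density=density,
                          weighting=weighting, n_frames=len(frames))
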