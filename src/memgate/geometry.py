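"""Geometric kernels: periodic distances, RMSD, axis angles, plane fits.

Periodic minimum-image convention is applied in x and y only: the
membrane normal is z and slab systems are assumed not to wrap across z,
which avoids spurious cross-leaflet contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import FrameWindow, Frame, Trajectory

__all__ = [
    "DistanceMatrixRequest",
    "BilayerReference",
    "min_image_distance",
    "min_image_displacements",
    "cross_distances",
    "pairs_within",
    "backbone_rmsd",
    "axis_angle_to_normal",
    "vector_angle_to_z",
    "fit_phosphorus_plane",
    "assign_leaflets",
]


@dataclass(frozen=True)
class DistanceMatrixRequest:
    group_a: tuple
    group_b: tuple
    cutoff: float
    pbc: bool = True

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        object.__setattr__(self, "group_a", tuple(self.group_a))
        object.__setattr__(self, "group_b", tuple(self.group_b))


@dataclass
class BilayerReference:
    """Phosphorus-plane reference of one leaflet.

    ``plane_z`` holds the per-frame mean z of the leaflet's phosphorus
    atoms; ``averaged_z`` is the time average over the analysis window
    (the default depth/snorkeling reference); ``leaflet_ids`` maps
    leaflet label -> phosphorus atom ids, fixed for the whole run.
    """

    plane_z: np.ndarray
    averaged_z: float
    window: FrameWindow
    leaflet_ids: dict
    # window-averaged plane z per leaflet label, when both are known
    leaflet_planes: dict = None


def min_image_displacements(delta: np.ndarray, box) -> np.ndarray:
    """Apply minimum image in x and y to displacement vectors (..., 3)."""
    delta = np.array(delta, dtype=float, copy=True)
    for ax in (0, 1):
        L = box[ax]
        delta[..., ax] -= L * np.round(delta[..., ax] / L)
    return delta


def min_image_distance(p1, p2, box) -> float:
    """Distance with minimum image in x/y; z is taken as-is."""
    if any(b <= 0 for b in box):
        raise ValueError("box lengths must be positive")
    d = min_image_displacements(np.asarray(p2, float) - np.asarray(p1, float),
                                box)
    return float(np.linalg.norm(d))


def cross_distances(coords: np.ndarray, ids_a, ids_b, box) -> np.ndarray:
    """(len(a), len(b)) distance matrix under the x/y minimum image."""
    a = coords[np.asarray(ids_a, dtype=int)]
    b = coords[np.asarray(ids_b, dtype=int)]
    delta = min_image_displacements(b[None, :, :] - a[:, None, :], box)
    return np.linalg.norm(delta, axis=-1)


def pairs_within(req: DistanceMatrixRequest, frame: Frame) -> set:
    """All unordered cross pairs with distance <= cutoff."""
    if not req.group_a or not req.group_b:
        raise ValueError("groups must be nonempty")
    if req.pbc:
        dm = cross_distances(frame.coords, req.group_a, req.group_b,
                             frame.box)
    else:
        a = frame.coords[np.asarray(req.group_a, dtype=int)]
        b = frame.coords[np.asarray(req.group_b, dtype=int)]
        dm = np.linalg.norm(b[None, :, :] - a[:, None, :], axis=-1)
    ii, jj = np.nonzero(dm <= req.cutoff)
    out = set()
    for i, j in zip(ii, jj):
        ai, bj = req.group_a[i], req.group_b[j]
        if ai != bj:
            out.add((min(ai, bj), max(ai, bj)))
    return out


def backbone_rmsd(traj: Trajectory, reference: Frame, atom_ids,
                  superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD over ``atom_ids`` against a reference frame.

    Uniform weights. With ``superpose=True`` (default) each frame is
    first optimally superposed (Kabsch rotation after centroid
    removal); with ``superpose=False`` coordinates are compared as-is,
    for trajectories already aligned to the reference.
    """
    atom_ids = np.asarray(atom_ids, dtype=int)
    if atom_ids.size == 0:
        raise ValueError("atom_ids must be nonempty")
    if superpose and atom_ids.size < 3:
        raise ValueError("superposition needs at least 3 atoms")
    ref = reference.coords[atom_ids]
    ref_c = ref - ref.mean(axis=0)
    out = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        mob = fr.coords[atom_ids]
        if superpose:
            mob_c = mob - mob.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_c, mob_c)
            diff = rot.apply(mob_c) - ref_c
        else:
            diff = mob - ref
        out[k] = np.sqrt((diff ** 2).sum() / atom_ids.size)
    return out


def vector_angle_to_z(vec: np.ndarray, fold: bool = True) -> float:
    """Angle (degrees) between ``vec`` and +z.

    ``fold=True`` reports the acute equivalent in [0, 90] (protein tilt
    convention); ``fold=False`` keeps the full [0, 180] range (lipid
    tail convention, where orientations above 150 deg and at or below
    45 deg mean different things).
    """
    vec = np.asarray(vec, dtype=float)
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        raise ValueError("zero-length axis vector")
    cosang = np.clip(vec[2] / norm, -1.0, 1.0)
    ang = float(np.degrees(np.arccos(cosang)))
    if fold and ang > 90.0:
        ang = 180.0 - ang
    return ang


def axis_angle_to_normal(frame: Frame, atom_a: int, atom_b: int) -> float:
    """Folded angle [0, 90] deg between the a->b axis and the bilayer normal."""
    v = frame.coords[atom_b] - frame.coords[atom_a]
    if np.linalg.norm(v) < 1e-12:
        raise ValueError(f"atoms {atom_a} and {atom_b} are coincident")
    return vector_angle_to_z(v, fold=True)


def fit_phosphorus_plane(traj: Trajectory, leaflet_ids,
                         window: FrameWindow) -> BilayerReference:
    """Per-frame mean z of the leaflet phosphorus atoms, plus its time
    average over ``window``."""
    leaflet_ids = np.asarray(leaflet_ids, dtype=int)
    if leaflet_ids.size == 0:
        raise ValueError("leaflet_ids must be nonempty")
    window = window.clipped(traj.n_frames)
    if len(window) == 0:
        raise ValueError("empty analysis window")
    plane_z = np.array([fr.coords[leaflet_ids, 2].mean()
                        for fr in traj.frames])
    averaged = float(plane_z[window.start_frame:window.end_frame + 1].mean())
    return BilayerReference(plane_z=plane_z, averaged_z=averaged,
                            window=window,
                            leaflet_ids={"fitted": list(map(int,
                                                            leaflet_ids))})


def assign_leaflets(traj: Trajectory, frame_index: int = 0) -> dict:
    """Split lipid phosphorus atoms into upper/lower leaflets.

    A lipid belongs to the leaflet whose side of the bilayer midplane
    (mean of all phosphorus z) its phosphorus occupies in
    ``frame_index``; the assignment is fixed thereafter (flip-flop is
    not tracked).
    """
    p_ids = [a.atom_id for a in traj.topology if "phosphorus" in a.flags]
    if not p_ids:
        raise ValueError("no phosphorus atoms in topology")
    z = traj.frames[frame_index].coords[p_ids, 2]
    mid = z.mean()
    upper = [i for i, zz in zip(p_ids, z) if zz >= mid]
    lower = [i for i, zz in zip(p_ids, z) if zz < mid]
    return {"upper": upper, "lower": lower}
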