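"""Per-lipid conformational classification.

A lipid tail is described by the vector from the glycerol C2 carbon to
the tail's terminal carbon (CHARMM C218/C316-style naming; the terminal
carbon is the highest-numbered carbon of the chain, overridable). The
tilt angle of that vector against the membrane normal is NOT folded:
values at or above 150 deg mean the tail points into the bilayer
normally (upper leaflet), values at or below 45 deg mean it has swung
up into a protein cavity.

Snorkeling: a tail whose terminal carbon rises above 5 Å below the
phosphorus plane for more than 1% of the analysed frames (strictly more
— exactly 1% does not qualify). For lower-leaflet lipids the criterion
is mirrored (terminal carbon below 5 Å above the lower plane).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FrameWindow, Trajectory, TopologyError
from .geometry import BilayerReference, min_image_displacements

__all__ = [
    "TailConformation",
    "tail_atoms",
    "tail_tilt_series",
    "terminal_z_series",
    "snorkel_fraction",
    "classify_snorkeling",
    "classify_insertion",
    "classify_tails",
    "count_lipids_under_gate",
    "_plane_for_leaflet",
]

SNORKEL_THRESHOLD_FRACTION = 0.01
SNORKEL_Z_OFFSET = -5.0       # Å relative to the phosphorus plane
INSERTED_MAX_TILT = 45.0      # deg
BILAYER_MIN_TILT = 150.0      # deg


@dataclass
class TailConformation:
    lipid_key: str
    tail: str                         # "sn1" or "sn2"
    tilt: np.ndarray                  # per-frame degrees, [0, 180]
    terminal_z: np.ndarray            # per-frame Å
    leaflet: str                      # "upper" / "lower"
    snorkel_fraction: float = 0.0
    classification: str = "bilayer"   # bilayer / snorkeling / inserted


def _lipid_residues(traj: Trajectory):
    res: dict = {}
    for a in traj.topology:
        if a.segment_id != "" and ("c2_carbon" in a.flags
                                   or "tail_terminal_carbon" in a.flags
                                   or "phosphorus" in a.flags):
            res.setdefault((a.segment_id, a.residue_id), []).append(a)
    return res


def tail_atoms(traj: Trajectory, lipid: tuple, tail: str,
               terminal_override: str | None = None) -> tuple:
    """(C2 atom id, terminal carbon atom id) for one lipid tail.

    ``lipid`` is (segment_id, residue_id); ``tail`` is "sn1" (C3x
    chain) or "sn2" (C2x chain). The terminal carbon defaults to the
    highest-numbered chain carbon; pass ``terminal_override`` (an atom
    name) for other lipid types.
    """
    if tail not in ("sn1", "sn2"):
        raise ValueError("tail must be 'sn1' or 'sn2'")
    prefix = "C3" if tail == "sn1" else "C2"
    atoms = [a for a in traj.topology
             if (a.segment_id, a.residue_id) == lipid]
    if not atoms:
        raise TopologyError(f"no such lipid {lipid}")
    c2 = next((a for a in atoms if "c2_carbon" in a.flags), None)
    if c2 is None:
        raise TopologyError(f"lipid {lipid} has no designated C2 carbon")
    if terminal_override is not None:
        term = next((a for a in atoms if a.name == terminal_override), None)
        if term is None:
            raise TopologyError(
                f"lipid {lipid} has no atom {terminal_override!r}")
        return c2.atom_id, term.atom_id
    chain = [a for a in atoms
             if a.name.startswith(prefix) and len(a.name) > 2
             and a.name[2:].isdigit()]
    if not chain:
        raise TopologyError(f"lipid {lipid} has no {tail} chain carbons")
    term = max(chain, key=lambda a: int(a.name[2:]))
    return c2.atom_id, term.atom_id


def tail_tilt_series(traj: Trajectory, lipid: tuple, tail: str,
                     terminal_override: str | None = None) -> np.ndarray:
    """Per-frame unfolded angle (deg, [0, 180]) between the
    C2->terminal-carbon vector and +z."""
    c2, term = tail_atoms(traj, lipid, tail, terminal_override)
    coords = traj.coords
    v = coords[:, term] - coords[:, c2]
    norm = np.linalg.norm(v, axis=-1)
    if np.any(norm < 1e-12):
        raise ValueError(f"degenerate tail vector for lipid {lipid}")
    cosang = np.clip(v[:, 2] / norm, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def terminal_z_series(traj: Trajectory, lipid: tuple, tail: str,
                      terminal_override: str | None = None) -> np.ndarray:
    _, term = tail_atoms(traj, lipid, tail, terminal_override)
    return traj.coords[:, term, 2]



def _plane_for_leaflet(ref: BilayerReference, leaflet: str) -> float:
    """Averaged phosphorus-plane z of the lipid's own leaflet.

    Falls back to mirroring the single fitted plane through z=0 for a
    symmetric slab when only one leaflet was fitted."""
    if getattr(ref, "leaflet_planes", None) and leaflet in ref.leaflet_planes:
        return ref.leaflet_planes[leaflet]
    if leaflet == "lower" and ref.averaged_z > 0:
        return -ref.averaged_z
    if leaflet == "upper" and ref.averaged_z < 0:
        return -ref.averaged_z
    return ref.averaged_z

def snorkel_fraction(terminal_z: np.ndarray, plane_z: float,
                     z_offset: float = SNORKEL_Z_OFFSET,
                     leaflet: str = "upper") -> float:
    """Fraction of frames with the terminal carbon above
    ``plane + z_offset`` (mirrored for the lower leaflet)."""
    if leaflet == "upper":
        hits = terminal_z > plane_z + z_offset
    else:
        hits = terminal_z < plane_z - z_offset
    return float(np.count_nonzero(hits)) / len(terminal_z)


def classify_snorkeling(conf: TailConformation, ref: BilayerReference,
                        threshold_fraction: float
                        = SNORKEL_THRESHOLD_FRACTION,
                        z_offset: float = SNORKEL_Z_OFFSET) -> bool:
    """True iff the terminal carbon spends strictly more than
    ``threshold_fraction`` of the frames above ``plane + z_offset``.

    The comparison is on frame counts (hits > threshold * n_frames), so
    exactly the threshold fraction does not qualify.
    """
    z = conf.terminal_z
    plane = _plane_for_leaflet(ref, conf.leaflet)
    if conf.leaflet == "upper":
        hits = int(np.count_nonzero(z > plane + z_offset))
    else:
        hits = int(np.count_nonzero(z < plane - z_offset))
    return hits > threshold_fraction * len(z)


def classify_insertion(tilt: np.ndarray,
                       inserted_max: float = INSERTED_MAX_TILT,
                       bilayer_min: float = BILAYER_MIN_TILT,
                       frame_interval: float = 1.0):
    """Per-frame state labels plus the longest inserted dwell.

    Returns ``(states, longest_inserted_dwell_ns)`` where states is an
    array of {"inserted", "bilayer", "intermediate"}.
    """
    tilt = np.asarray(tilt, dtype=float)
    states = np.where(tilt <= inserted_max + 1e-9, "inserted",
                      np.where(tilt >= bilayer_min - 1e-9, "bilayer",
                               "intermediate"))
    longest = 0
    run = 0
    for s in states:
        run = run + 1 if s == "inserted" else 0
        longest = max(longest, run)
    return states, longest * frame_interval


def classify_tails(traj: Trajectory, ref: BilayerReference,
                   window: FrameWindow | None = None,
                   threshold_fraction: float = SNORKEL_THRESHOLD_FRACTION,
                   z_offset: float = SNORKEL_Z_OFFSET) -> list:
    """TailConformation for every tail of every lipid.

    Classification precedence: a tail whose median tilt is in the
    inserted band is ``inserted``; otherwise ``snorkeling`` if the
    snorkeling criterion holds; otherwise ``bilayer``.
    """
    if window is None:
        window = FrameWindow(0, traj.n_frames - 1)
    window = window.clipped(traj.n_frames)
    sl = slice(window.start_frame, window.end_frame + 1)
    upper = set(ref.leaflet_ids.get("upper", ()))
    out = []
    for lipid in sorted(_lipid_residues(traj)):
        p = next((a for a in traj.topology
                  if (a.segment_id, a.residue_id) == lipid
                  and "phosphorus" in a.flags), None)
        leaflet = "upper" if (p is not None and p.atom_id in upper) \
            else "lower"
        for tail in ("sn1", "sn2"):
            try:
                tilt = tail_tilt_series(traj, lipid, tail)[sl]
                tz = terminal_z_series(traj, lipid, tail)[sl]
            except TopologyError:
                continue
            conf = TailConformation(
                lipid_key=f"{lipid[0]}/{lipid[1]}", tail=tail, tilt=tilt,
                terminal_z=tz, leaflet=leaflet)
            conf.snorkel_fraction = snorkel_fraction(
                tz, _plane_for_leaflet(ref, leaflet), z_offset, leaflet)
            med = float(np.median(tilt)) if leaflet == "upper" \
                else 180.0 - float(np.median(tilt))
            if med <= INSERTED_MAX_TILT:
                conf.classification = "inserted"
            elif classify_snorkeling(conf, ref, threshold_fraction,
                                     z_offset):
                conf.classification = "snorkeling"
            else:
                conf.classification = "bilayer"
            out.append(conf)
    return out


def _deviant_frame_mask(traj: Trajectory, lipid: tuple, leaflet: str,
                        ref: BilayerReference, z_offset: float) -> np.ndarray:
    """Per-frame 'deviant tail' predicate: any tail snorkeling (terminal
    carbon above plane + z_offset) or in the inserted tilt band."""
    mask = np.zeros(traj.n_frames, dtype=bool)
    for tail in ("sn1", "sn2"):
        try:
            tz = terminal_z_series(traj, lipid, tail)
            tilt = tail_tilt_series(traj, lipid, tail)
        except TopologyError:
            continue
        plane = _plane_for_leaflet(ref, leaflet)
        if leaflet == "upper":
            snork = tz > plane + z_offset
            eff_tilt = tilt
        else:
            snork = tz < plane - z_offset
            eff_tilt = 180.0 - tilt
        mask |= snork | (eff_tilt <= INSERTED_MAX_TILT + 1e-9)
    return mask


def count_lipids_under_gate(traj: Trajectory, footprint_ids,
                            ref: BilayerReference,
                            radius: float = 15.0,
                            window: FrameWindow | None = None,
                            z_offset: float = SNORKEL_Z_OFFSET
                            ) -> pd.DataFrame:
    """Per-frame count of conformationally deviant lipids under the
    protein footprint, with the opposite-leaflet baseline.

    A lipid counts when its phosphorus lies within ``radius`` (in-plane
    minimum-image distance) of the footprint centroid in that frame AND
    a tail is deviant (snorkeling or inserted). The baseline applies
    the same deviant predicate to the whole opposite leaflet with no
    radius restriction.

    Columns: frame, time_ns, under_gate_count, opposite_leaflet_count.
    """
    footprint_ids = list(footprint_ids)
    if not footprint_ids:
        raise ValueError("footprint must be nonempty")
    if window is None:
        window = FrameWindow(0, traj.n_frames - 1)
    window = window.clipped(traj.n_frames)
    proximal_name = ref.leaflet_ids.get("proximal_name", "upper")
    opposite_name = "lower" if proximal_name == "upper" else "upper"
    prox_p = set(ref.leaflet_ids.get(proximal_name, ()))
    opp_p = set(ref.leaflet_ids.get(opposite_name, ()))

    lipids = []
    for lipid in sorted(_lipid_residues(traj)):
        p = next((a for a in traj.topology
                  if (a.segment_id, a.residue_id) == lipid
                  and "phosphorus" in a.flags), None)
        if p is None:
            continue
        if p.atom_id in prox_p:
            lipids.append((lipid, p.atom_id, proximal_name, True))
        elif p.atom_id in opp_p:
            lipids.append((lipid, p.atom_id, opposite_name, False))

    deviant = {lipid: _deviant_frame_mask(traj, lipid, leaflet, ref,
                                          z_offset)
               for lipid, _, leaflet, _ in lipids}

    rows = []
    for f in window.frames():
        fr = traj.frames[f]
        centroid = fr.coords[footprint_ids, :2].mean(axis=0)
        n_gate = 0
        n_opp = 0
        for lipid, p_id, leaflet, is_prox in lipids:
            if not deviant[lipid][f]:
                continue
            if is_prox:
                d = fr.coords[p_id, :2] - centroid
                d = min_image_displacements(
                    np.array([d[0], d[1], 0.0]), fr.box)
                if np.hypot(d[0], d[1]) <= radius:
                    n_gate += 1
            else:
                n_opp += 1
        rows.append({"frame": f, "time_ns": fr.time,
                     "under_gate_count": n_gate,
                     "opposite_leaflet_count": n_opp})
    return pd.DataFrame(rows)
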