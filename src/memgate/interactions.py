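"""Hydrophobic-contact, hydrogen-bond and cation-pi inventories.

All three detectors share the same persistence rule: the geometric
criterion must hold in at least ``min_consecutive`` saved frames with no
gap (a single frame below criterion terminates a run). Criteria:

* hydrophobic contact: two unbound apolar candidate atoms within 3 Å
  (pairs that are covalently bonded, 1-3 connected, or within the same
  residue are excluded);
* hydrogen bond: acceptor-to-hydrogen distance <= 2.4 Å and a
  donor-hydrogen-acceptor angle >= 130 deg, simultaneously;
* cation-pi: every atom of an aromatic ring within (strictly below)
  7 Å of the choline nitrogen.

Inclusive thresholds are compared with a 1e-9 Å / degree epsilon so a
geometry constructed exactly at the printed boundary is accepted
irrespective of the floating-point rounding of the constant.

Residue-level aggregation: one or more qualifying atom contacts between
two residues (or a residue and a lipid molecule) means those partners
engage in the interaction; the replica-consensus inventory retains only
partner pairs detected in every replica.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FrameWindow, Trajectory, TopologyError, aromatic_rings


__all__ = [
    "ContactEvent",
    "InteractionInventory",
    "detect_hydrophobic",
    "detect_hbonds",
    "detect_cation_pi",
    "build_inventory",
    "replica_consensus",
    "windowed_contact_series",
    "active_mask",
]

EPS = 1e-9
_PAIR_CHUNK = 20000


@dataclass(frozen=True)
class ContactEvent:
    """One persistent interaction instance.

    ``atoms`` is (i, j) for hydrophobic, (donor, hydrogen, acceptor)
    for hydrogen bonds, and ring atoms + nitrogen for cation-pi.
    ``residue_pair`` uses ``segment/RESNAMEresid`` keys, protein side
    first where applicable.
    """

    kind: str
    atoms: tuple
    residue_pair: tuple
    window: FrameWindow

    def duration_frames(self) -> int:
        return len(self.window)


def _runs(mask: np.ndarray):
    """Maximal runs of True as (start, end) inclusive pairs."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def _residue_pair(traj: Trajectory, i: int, j: int) -> tuple:
    a, b = traj.topology[i], traj.topology[j]
    ka, kb = a.residue_key, b.residue_key
    from .core import is_protein_atom
    pa, pb = is_protein_atom(a), is_protein_atom(b)
    if pb and not pa:
        return (kb, ka)
    if pa and not pb:
        return (ka, kb)
    return (ka, kb) if ka <= kb else (kb, ka)


def _excluded_pairs(traj: Trajectory) -> set:
    """1-2 and 1-3 connected atom pairs (unordered)."""
    nb = traj.bonded_neighbors()
    out = set()
    for i, js in nb.items():
        for j in js:
            out.add((min(i, j), max(i, j)))
            for k in nb[j]:
                if k != i:
                    out.add((min(i, k), max(i, k)))
    return out


def _pair_distance_series(traj: Trajectory, pairs: np.ndarray) -> np.ndarray:
    """(n_frames, n_pairs) minimum-image distances, chunked over pairs."""
    coords = traj.coords
    boxes = np.array([fr.box for fr in traj.frames])
    n_pairs = pairs.shape[0]
    out = np.empty((traj.n_frames, n_pairs))
    for lo in range(0, n_pairs, _PAIR_CHUNK):
        sl = slice(lo, min(lo + _PAIR_CHUNK, n_pairs))
        delta = coords[:, pairs[sl, 0]] - coords[:, pairs[sl, 1]]
        for ax in (0, 1):
            L = boxes[:, ax][:, None]
            delta[..., ax] -= L * np.round(delta[..., ax] / L)
        out[:, sl] = np.linalg.norm(delta, axis=-1)
    return out


def _events_from_masks(traj: Trajectory, kind: str, atom_tuples,
                       mask: np.ndarray, min_consecutive: int,
                       pair_keys) -> list:
    events = []
    for col, atoms in enumerate(atom_tuples):
        for start, end in _runs(mask[:, col]):
            if end - start + 1 >= min_consecutive:
                events.append(ContactEvent(
                    kind=kind, atoms=tuple(int(a) for a in atoms),
                    residue_pair=pair_keys[col],
                    window=FrameWindow(int(start), int(end))))
    events.sort(key=lambda e: (e.window.start_frame, e.residue_pair,
                               e.atoms))
    return events


def detect_hydrophobic(traj: Trajectory, candidates=None, cutoff: float = 3.0,
                       min_consecutive: int = 2) -> list:
    """Persistent apolar-pair contacts (<= ``cutoff``, default 3 Å, for
    at least ``min_consecutive`` consecutive frames).

    ``candidates`` defaults to atoms flagged ``hydrophobic_candidate``
    (carbons with no N/O/S/P neighbour plus Cys/Met sulfur); override
    to reproduce a bespoke candidate table.
    """
    if candidates is None:
        candidates = [a.atom_id for a in traj.topology
                      if "hydrophobic_candidate" in a.flags]
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        import warnings
        warnings.warn("empty hydrophobic candidate list")
        return []
    excluded = _excluded_pairs(traj)
    res_of = {a.atom_id: (a.segment_id, a.residue_id)
              for a in traj.topology}
    pairs = []
    for x in range(len(candidates)):
        for y in range(x + 1, len(candidates)):
            i, j = candidates[x], candidates[y]
            if res_of[i] == res_of[j] or (i, j) in excluded:
                continue
            pairs.append((i, j))
    if not pairs:
        return []
    pairs = np.array(pairs, dtype=int)
    dist = _pair_distance_series(traj, pairs)
    mask = dist <= cutoff + EPS
    keys = [_residue_pair(traj, i, j) for i, j in pairs]
    return _events_from_masks(traj, "hydrophobic", pairs, mask,
                              min_consecutive, keys)


def _donor_of_hydrogens(traj: Trajectory, hydrogens) -> dict:
    nb = traj.bonded_neighbors()
    donor_of = {}
    for h in hydrogens:
        heavies = [j for j in nb[h]
                   if "hbond_donor_heavy" in traj.topology[j].flags]
        if len(heavies) != 1:
            raise TopologyError(
                f"hydrogen {h} bonded to {len(heavies)} donor heavy "
                f"atoms (need exactly 1)")
        donor_of[h] = heavies[0]
    return donor_of


def detect_hbonds(traj: Trajectory, donors=None, hydrogens=None,
                  acceptors=None, d_ha: float = 2.4,
                  angle_min: float = 130.0,
                  min_consecutive: int = 2) -> list:
    """Persistent hydrogen bonds: H...A distance <= ``d_ha`` AND
    donor-H-acceptor angle >= ``angle_min``, both in every frame of a
    run of at least ``min_consecutive`` frames."""
    if hydrogens is None:
        hydrogens = [a.atom_id for a in traj.topology
                     if "hbond_hydrogen" in a.flags]
    if acceptors is None:
        acceptors = [a.atom_id for a in traj.topology
                     if "hbond_acceptor" in a.flags]
    donor_of = _donor_of_hydrogens(traj, hydrogens)
    if donors is not None:
        donors = set(int(d) for d in donors)
        hydrogens = [h for h in hydrogens if donor_of[h] in donors]
    res_of = {a.atom_id: (a.segment_id, a.residue_id)
              for a in traj.topology}

    triples = []
    for h in hydrogens:
        d = donor_of[h]
        for a in acceptors:
            if a == d or a == h or res_of[a] == res_of[h]:
                continue
            triples.append((d, h, a))
    if not triples:
        return []
    triples = np.array(triples, dtype=int)

    coords = traj.coords
    boxes = np.array([fr.box for fr in traj.frames])
    n = triples.shape[0]
    mask = np.empty((traj.n_frames, n), dtype=bool)
    for lo in range(0, n, _PAIR_CHUNK):
        sl = slice(lo, min(lo + _PAIR_CHUNK, n))
        d_xyz = coords[:, triples[sl, 0]]
        h_xyz = coords[:, triples[sl, 1]]
        a_xyz = coords[:, triples[sl, 2]]
        ha = a_xyz - h_xyz
        hd = d_xyz - h_xyz
        for ax in (0, 1):
            L = boxes[:, ax][:, None]
            ha[..., ax] -= L * np.round(ha[..., ax] / L)
            hd[..., ax] -= L * np.round(hd[..., ax] / L)
        dist = np.linalg.norm(ha, axis=-1)
        cosang = np.einsum("fij,fij->fi", ha, hd) / np.maximum(
            dist * np.linalg.norm(hd, axis=-1), 1e-300)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        mask[:, sl] = (dist <= d_ha + EPS) & (ang >= angle_min - EPS)
    keys = [_residue_pair(traj, int(t[0]), int(t[2])) for t in triples]
    return _events_from_masks(traj, "hbond", triples, mask,
                              min_consecutive, keys)


def detect_cation_pi(traj: Trajectory, rings=None, cations=None,
                     cutoff: float = 7.0,
                     min_consecutive: int = 2) -> list:
    """Persistent cation-pi interactions: EVERY ring-atom-to-choline-N
    distance strictly below ``cutoff`` in each frame of the run."""
    if rings is None:
        rings = aromatic_rings(traj.topology)
    if cations is None:
        cations = [a.atom_id for a in traj.topology
                   if "choline_nitrogen" in a.flags]
    for ring in rings:
        if len(ring) not in (5, 6):
            raise TopologyError(
                f"aromatic ring must have 5 or 6 atoms, got {len(ring)}")
    if not rings or not cations:
        return []
    coords = traj.coords
    boxes = np.array([fr.box for fr in traj.frames])
    combos = [(tuple(ring), int(n)) for ring in rings for n in cations]
    mask = np.empty((traj.n_frames, len(combos)), dtype=bool)
    for col, (ring, n) in enumerate(combos):
        delta = coords[:, list(ring)] - coords[:, n][:, None, :]
        for ax in (0, 1):
            L = boxes[:, ax][:, None]
            delta[..., ax] -= L * np.round(delta[..., ax] / L)
        dmax = np.linalg.norm(delta, axis=-1).max(axis=1)
        mask[:, col] = dmax < cutoff
    atom_tuples = [ring + (n,) for ring, n in combos]
    keys = [_residue_pair(traj, ring[0], n) for ring, n in combos]
    return _events_from_masks(traj, "cation_pi", atom_tuples, mask,
                              min_consecutive, keys)


# --------------------------------------------------------------------------
# Inventories
# --------------------------------------------------------------------------


def active_mask(events, n_frames: int, selection=None) -> dict:
    """Per residue-pair boolean presence over frames (union of events)."""
    out: dict = {}
    for ev in events:
        if selection is not None and ev.residue_pair[0] not in selection \
                and ev.residue_pair[1] not in selection:
            continue
        m = out.setdefault((ev.kind,) + ev.residue_pair,
                           np.zeros(n_frames, dtype=bool))
        m[ev.window.start_frame:ev.window.end_frame + 1] = True
    return out


@dataclass
class InteractionInventory:
    """Residue-partner interaction summary.

    ``table`` columns: kind, residue, partner, partner_species,
    occupancy (fraction of analysis-window frames), n_events,
    mean_duration_ns, max_duration_ns, consensus (set by
    :func:`replica_consensus`).
    """

    table: pd.DataFrame
    n_frames: int
    frame_interval: float

    def keys(self) -> set:
        return set(zip(self.table["kind"], self.table["residue"],
                       self.table["partner"]))

    def by_species(self) -> pd.DataFrame:
        """Occupancy pooled by partner species (lipid resname)."""
        return (self.table.groupby(["kind", "residue", "partner_species"])
                .agg(occupancy=("occupancy", "sum"),
                     n_events=("n_events", "sum"))
                .reset_index())


def build_inventory(events, n_frames: int, frame_interval: float,
                    window: FrameWindow | None = None
                    ) -> InteractionInventory:
    """Aggregate events to the residue-partner level over ``window``
    (default: the whole trajectory)."""
    if window is None:
        window = FrameWindow(0, max(n_frames - 1, 0))
    wlen = len(window)
    rows = []
    groups: dict = {}
    for ev in events:
        groups.setdefault((ev.kind,) + ev.residue_pair, []).append(ev)
    for (kind, res, part), evs in sorted(groups.items()):
        m = np.zeros(n_frames, dtype=bool)
        durations = []
        for ev in evs:
            m[ev.window.start_frame:ev.window.end_frame + 1] = True
            durations.append(len(ev.window) * frame_interval)
        occ = m[window.start_frame:window.end_frame + 1].sum() / wlen
        species = part.split("/")[-1].rstrip("0123456789")
        rows.append({
            "kind": kind, "residue": res, "partner": part,
            "partner_species": species,
            "occupancy": float(occ), "n_events": len(evs),
            "mean_duration_ns": float(np.mean(durations)),
            "max_duration_ns": float(np.max(durations)),
            "consensus": True,
        })
    cols = ["kind", "residue", "partner", "partner_species", "occupancy",
            "n_events", "mean_duration_ns", "max_duration_ns", "consensus"]
    return InteractionInventory(pd.DataFrame(rows, columns=cols),
                                n_frames, frame_interval)


def replica_consensus(inventories) -> InteractionInventory:
    """Keep residue-partner interactions present in every replica.

    The returned table carries per-replica occupancies
    (``occupancy_rep{k}``) alongside the mean; the per-replica detail is
    preserved in the inputs.
    """
    inventories = list(inventories)
    if not inventories:
        raise ValueError("need at least one inventory")
    common = set.intersection(*(inv.keys() for inv in inventories))
    rows = []
    for key in sorted(common):
        kind, res, part = key
        occs = []
        base = None
        for k, inv in enumerate(inventories):
            sub = inv.table[(inv.table["kind"] == kind)
                            & (inv.table["residue"] == res)
                            & (inv.table["partner"] == part)]
            occs.append(float(sub["occupancy"].iloc[0]))
            if base is None:
                base = sub.iloc[0].to_dict()
        row = dict(base)
        row["occupancy"] = float(np.mean(occs))
        row["consensus"] = True
        for k, o in enumerate(occs):
            row[f"occupancy_rep{k}"] = o
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        cols = list(inventories[0].table.columns) + [
            f"occupancy_rep{k}" for k in range(len(inventories))]
        table = pd.DataFrame(columns=cols)
    return InteractionInventory(table, inventories[0].n_frames,
                                inventories[0].frame_interval)


def windowed_contact_series(events, window_width: float, selection,
                            n_frames: int,
                            frame_interval: float) -> pd.DataFrame:
    """Mean instantaneous residue-level contact count per time window.

    ``window_width`` (ns, default use 20) must be a positive multiple of
    the frame interval; ``selection`` is an iterable of residue keys
    whose contacts are counted.
    """
    ratio = window_width / frame_interval
    w = int(round(ratio))
    if w < 1 or abs(ratio - w) > 1e-9:
        raise ValueError(
            "window_width must be a positive multiple of frame_interval")
    selection = set(selection)
    if not selection:
        return pd.DataFrame(columns=["window_start_ns", "window_end_ns",
                                     "mean_contacts"])
    masks = active_mask(events, n_frames, selection=selection)
    counts = np.zeros(n_frames)
    for m in masks.values():
        counts += m
    rows = []
    for lo in range(0, n_frames, w):
        hi = min(lo + w, n_frames)
        rows.append({"window_start_ns": lo * frame_interval,
                     "window_end_ns": hi * frame_interval,
                     "mean_contacts": float(counts[lo:hi].mean())})
    return pd.DataFrame(rows)
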