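"""Synthetic protein-membrane trajectories with planted, logged events.

The generator builds a toy bilayer slab (two leaflets of simplified
phosphatidylcholine-like lipids on a grid: choline N + methyls,
phosphorus, glycerol with the C2 carbon, an ester oxygen, and two acyl
tails with CHARMM-style ``C2x``/``C3x`` carbon naming) plus a rigid
pseudo-protein whose residues include analogues of the gate residues
W473, S476 (loop 1) and W562, P564 (loop 4), the helix anchors A565 and
T591, and a few filler residues. Scheduled events are realized
geometrically, frame by frame, and an :class:`EventLog` records exactly
what was planted, so every detector can be validated against ground
truth without any real trajectory.

There is no physical realism here — no force field, no thermodynamics:
the protein is rigid except scripted displacements, and lipid atoms are
moved directly. That isolates detector behaviour from conformational
noise.

Event kinds and how they are realized (all windows are inclusive frame
ranges; "present" is the frame range where the interaction/state holds):

``binding``
    the protein starts 15 Å above its bound pose and descends linearly
    over the window, then stays bound (min heavy-atom distance to the
    bilayer ~3.5 Å). Present window: frames from the first sustained
    crossing of the 4 Å contact criterion to the end.
``gate_open``
    the loop-1 block (W473..S476 analogues) is displaced laterally so
    the W473-P564 distance changes from ~7 Å to ~15 Å inside the window.
``hbond_on`` / ``hbond_off``
    a lipid ester oxygen is placed at 1.9 Å from the serine hydroxyl
    hydrogen with a donor-hydrogen-acceptor angle of 165 deg while the
    bond is present (``on``: inside the window; ``off``: from frame 0
    up to the window start), and restored to its template position
    otherwise.
``contact_on`` / ``contact_off``
    a mid-chain lipid tail carbon is placed 2.5 Å from an exposed
    apolar protein carbon while the contact is present.
``snorkel``
    a tail terminal carbon is raised to 3 Å below the phosphorus plane
    (well above the 5-Å snorkeling criterion) inside the window.
``tail_insertion``
    the designated sn-2 tail is laid along a 30-deg tilt vector
    (inserted) inside the window and a 160-deg vector (bilayer)
    outside it.

Randomness (positional noise only) uses ``numpy.random.default_rng``
(PCG64), so the same seed reproduces trajectories bit-for-bit across
platforms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    AtomRecord, Frame, FrameWindow, ReplicaSet, Trajectory, assign_roles,
    write_pdb, write_text_frames,
)

__all__ = [
    "ScenarioError",
    "ScenarioEvent",
    "EventRecord",
    "EventLog",
    "ScenarioSpec",
    "build_bilayer_slab",
    "build_scenario",
    "demo_events",
    "write_scenario",
]

EVENT_KINDS = (
    "binding", "gate_open", "hbond_on", "hbond_off",
    "contact_on", "contact_off", "snorkel", "tail_insertion",
)

BINDING_CONTACT_CUTOFF = 4.0   # Å, ground-truth contact criterion
BOUND_MIN_DISTANCE = 3.5       # Å, protein-bilayer gap in the bound pose
UNBOUND_LIFT = 15.0            # Å above the bound pose before binding
GATE_CLOSED_D1 = 7.0           # Å, W473-P564 analogue Ca-Ca distance
GATE_OPEN_D1 = 15.0
HBOND_HA = 1.9                 # Å, planted H...A distance
HBOND_ANGLE = 165.0            # deg, planted D-H-A angle
CONTACT_DISTANCE = 2.5         # Å, planted apolar pair distance
SNORKEL_RISE = 3.0             # Å below the phosphorus plane when snorkeling
TAIL_TILT_BILAYER = 160.0      # deg
TAIL_TILT_INSERTED = 30.0      # deg


class ScenarioError(ValueError):
    """Invalid or conflicting scenario specification."""


@dataclass(frozen=True)
class ScenarioEvent:
    kind: str
    window: FrameWindow
    params: tuple = ()   # sorted (key, value) pairs; see ScenarioSpec

    def param(self, key, default=None):
        for k, v in self.params:
            if k == key:
                return v
        return default


def _event(kind: str, start: int, end: int, **params) -> ScenarioEvent:
    if kind not in EVENT_KINDS:
        raise ScenarioError(f"unknown event kind {kind!r}")
    return ScenarioEvent(kind, FrameWindow(start, end),
                         tuple(sorted(params.items())))


@dataclass(frozen=True)
class EventRecord:
    """Ground truth for one planted event.

    ``window`` is the scheduled window from the spec; ``present_window``
    is the frame range over which the interaction/state actually holds
    in the noiseless geometry (for ``*_off`` events the two differ).
    """

    kind: str
    atom_ids: tuple
    window: FrameWindow
    present_window: FrameWindow

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "atom_ids": list(self.atom_ids),
            "window": [self.window.start_frame, self.window.end_frame],
            "present_window": [self.present_window.start_frame,
                               self.present_window.end_frame],
        }


@dataclass
class EventLog:
    scenario_id: str
    records: list = field(default_factory=list)

    def by_kind(self, kind: str) -> list:
        return [r for r in self.records if r.kind == kind]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"scenario_id": self.scenario_id,
             "records": [r.to_dict() for r in self.records]},
            indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "EventLog":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        data = json.loads(text)
        recs = [EventRecord(
                    kind=r["kind"], atom_ids=tuple(r["atom_ids"]),
                    window=FrameWindow(*r["window"]),
                    present_window=FrameWindow(*r["present_window"]))
                for r in data["records"]]
        return cls(scenario_id=data["scenario_id"], records=recs)


@dataclass
class ScenarioSpec:
    """Everything needed to build a deterministic toy scenario.

    Defaults emulate one bound-state system at desk scale: a 2-by-16
    lipid slab with the phosphorus planes at +/-20 Å, 200 frames at
    10 ns spacing (a 2-microsecond trajectory), and optional isotropic
    positional noise.
    """

    n_lipids_per_leaflet: int = 16
    n_frames: int = 200
    frame_interval: float = 10.0     # ns
    noise_sigma: float = 0.0         # Å
    seed: int = 0
    n_replicas: int = 1
    events: tuple = ()
    # lipid template
    tail_length: int = 8             # carbons per tail
    lipid_spacing: float = 8.0       # Å grid spacing
    z0: float = 20.0                 # Å phosphorus plane half-height
    lipid_resname: str = "TOYL"

    def __post_init__(self):
        if self.n_lipids_per_leaflet < 4:
            raise ScenarioError("need at least 4 lipids per leaflet")
        if self.noise_sigma < 0:
            raise ScenarioError("noise_sigma must be >= 0")
        if self.n_frames < 1:
            raise ScenarioError("need at least one frame")
        for ev in self.events:
            if ev.window.end_frame >= self.n_frames:
                raise ScenarioError(
                    f"{ev.kind} window {ev.window} exceeds "
                    f"n_frames={self.n_frames}")

    def event(self, kind: str, start: int, end: int,
              **params) -> "ScenarioSpec":
        """Return a copy with one more scheduled event."""
        from dataclasses import replace
        return replace(self, events=self.events
                       + (_event(kind, start, end, **params),))


# --------------------------------------------------------------------------
# Templates
# --------------------------------------------------------------------------


def _lipid_atoms(spec: ScenarioSpec, resid: int, segid: str, sign: int,
                 x: float, y: float):
    """One lipid: (name, element, offset) list, local bonds.

    ``sign`` +1 for the upper leaflet, -1 for the lower (geometry
    mirrored through z=0). Offsets are relative to (x, y, 0).
    """
    z0 = spec.z0
    L = spec.tail_length
    atoms = []       # (name, element, (x, y, z))
    bonds = []       # local index pairs

    def add(name, elem, dx, dy, dz):
        atoms.append((name, elem, (x + dx, y + dy, sign * dz)))
        return len(atoms) - 1

    p = add("P", "P", 0.0, 0.0, z0)
    n = add("N", "N", 1.0, 0.0, z0 + 3.0)
    c13 = add("C13", "C", 2.4, 0.0, z0 + 3.0)
    c14 = add("C14", "C", 1.0, 1.4, z0 + 3.0)
    c15 = add("C15", "C", 1.0, -1.4, z0 + 3.0)
    c1 = add("C1", "C", 0.0, 0.0, z0 - 2.5)
    c2 = add("C2", "C", 1.2, 0.0, z0 - 3.5)
    c3 = add("C3", "C", -1.2, 0.0, z0 - 3.5)
    o21 = add("O21", "O", 1.2, 1.2, z0 - 4.5)
    bonds += [(p, n), (n, c13), (n, c14), (n, c15),
              (p, c1), (c1, c2), (c2, c3), (c2, o21)]
    prev = c2
    for k in range(L):                       # sn-2 tail: C22..C2{L+1}
        idx = add(f"C2{k + 2}", "C", 1.2, 0.0, z0 - 5.0 - 1.5 * k)
        bonds.append((prev, idx))
        prev = idx
    prev = c3
    for k in range(L):                       # sn-1 tail: C32..C3{L+1}
        idx = add(f"C3{k + 2}", "C", -1.2, 0.0, z0 - 5.0 - 1.5 * k)
        bonds.append((prev, idx))
        prev = idx
    return atoms, bonds


def _hexagon(center, radius=1.39):
    cx, cy, cz = center
    pts = []
    for k in range(6):
        a = math.radians(60.0 * k)
        pts.append((cx + radius * math.cos(a),
                    cy + radius * math.sin(a), cz))
    return pts


def _protein_atoms():
    """Rigid pseudo-protein in local coordinates (membrane-facing face
    at z ~ -1; gate closed: W473-P564 Ca-Ca distance = 7 Å).

    All inter-residue apolar carbon pairs are kept farther than 3.2 Å
    apart so an event-free scenario produces no hydrophobic contacts.
    """
    atoms = []   # (name, element, resid, resname, (x, y, z))
    bonds = []

    def add(name, elem, resid, resname, xyz):
        atoms.append((name, elem, resid, resname, xyz))
        return len(atoms) - 1

    # loop 1 (Omega-1 analogue): W473 G474 A475 S476
    ca473 = add("CA", "C", 473, "TRP", (0.0, 0.0, 2.0))
    cb473 = add("CB", "C", 473, "TRP", (0.0, 0.0, 0.6))
    ring473 = [add(nm, "C", 473, "TRP", pt) for nm, pt in zip(
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
        _hexagon((0.0, 0.0, -0.8)))]
    bonds += [(ca473, cb473), (cb473, ring473[0])]
    bonds += [(ring473[i], ring473[(i + 1) % 6]) for i in range(6)]

    ca474 = add("CA", "C", 474, "GLY", (3.6, 0.0, 3.2))
    ca475 = add("CA", "C", 475, "ALA", (7.2, -1.0, 3.6))
    cb475 = add("CB", "C", 475, "ALA", (7.2, -1.0, 2.2))
    bonds.append((ca475, cb475))

    ca476 = add("CA", "C", 476, "SER", (6.0, 2.5, 2.2))
    cb476 = add("CB", "C", 476, "SER", (6.0, 3.2, 0.9))
    og476 = add("OG", "O", 476, "SER", (6.0, 3.9, -0.2))
    hg476 = add("HG1", "H", 476, "SER", (6.0, 3.9, -1.2))
    bonds += [(ca476, cb476), (cb476, og476), (og476, hg476)]

    # loop 4 (Omega-4 analogue): W562 A563 P564
    ca562 = add("CA", "C", 562, "TRP", (6.0, 7.0, 2.0))
    cb562 = add("CB", "C", 562, "TRP", (6.0, 7.0, 0.6))
    ring562 = [add(nm, "C", 562, "TRP", pt) for nm, pt in zip(
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
        _hexagon((6.0, 7.0, -0.8)))]
    bonds += [(ca562, cb562), (cb562, ring562[0])]
    bonds += [(ring562[i], ring562[(i + 1) % 6]) for i in range(6)]

    ca563 = add("CA", "C", 563, "ALA", (3.0, 6.6, 5.2))
    ca564 = add("CA", "C", 564, "PRO", (0.0, 7.0, 2.0))
    cb564 = add("CB", "C", 564, "PRO", (0.0, 7.0, 0.6))
    bonds.append((ca564, cb564))

    # helix alpha-4: A565 ... T591, axis at 40 deg from the normal
    ax = (math.sin(math.radians(40.0)), 0.0, math.cos(math.radians(40.0)))
    base = np.array([3.0, 10.5, 4.0])
    ca565 = add("CA", "C", 565, "ALA", tuple(base))
    cb565 = add("CB", "C", 565, "ALA", tuple(base + (0.0, 1.4, 0.0)))
    bonds.append((ca565, cb565))
    for rid, rname, t in ((570, "LEU", 5.0), (580, "VAL", 12.0)):
        pos = base + t * np.array(ax)
        ca = add("CA", "C", rid, rname, tuple(pos))
        cb = add("CB", "C", rid, rname, tuple(pos + (0.0, 1.4, 0.0)))
        bonds.append((ca, cb))
    tip = base + 20.0 * np.array(ax)
    ca591 = add("CA", "C", 591, "THR", tuple(tip))
    cb591 = add("CB", "C", 591, "THR", tuple(tip + (0.0, 1.4, 0.0)))
    og591 = add("OG1", "O", 591, "THR", tuple(tip + (0.0, 2.4, 0.8)))
    hg591 = add("HG1", "H", 591, "THR", tuple(tip + (0.0, 2.4, 1.8)))
    bonds += [(ca591, cb591), (cb591, og591), (og591, hg591)]
    return atoms, bonds


OMEGA1_RESIDS = (473, 474, 475, 476)


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------


def _grid_positions(spec: ScenarioSpec):
    g = math.ceil(math.sqrt(spec.n_lipids_per_leaflet))
    box_xy = g * spec.lipid_spacing
    center = box_xy / 2.0
    slots = [((c + 0.5) * spec.lipid_spacing, (r + 0.5) * spec.lipid_spacing)
             for r in range(g) for c in range(g)]
    slots.sort(key=lambda p: ((p[0] - center) ** 2 + (p[1] - center) ** 2,
                              p))
    return slots[:spec.n_lipids_per_leaflet], box_xy


@dataclass
class _Scenario:
    """Assembled template: topology, base coordinates, index maps."""

    topology: list
    bonds: list
    base: np.ndarray                  # (n_atoms, 3) template coordinates
    box: tuple
    protein_ids: np.ndarray
    omega1_ids: np.ndarray
    lipid_atom_ids: dict              # (leaflet, rank) -> {name: atom_id}
    lipid_order: dict                 # leaflet -> [rank...] nearest-first
    anchor: dict                      # (resid, name) -> atom_id


def _assemble(spec: ScenarioSpec) -> _Scenario:
    slots, box_xy = _grid_positions(spec)
    box = (box_xy, box_xy, 2.0 * (spec.z0 + 55.0))
    center = box_xy / 2.0

    names, elements, resids, resnames, segids = [], [], [], [], []
    coords, bonds = [], []
    anchor = {}

    prot_atoms, prot_bonds = _protein_atoms()
    prot_span = max(p[4][0] for p in prot_atoms) - \
        min(p[4][0] for p in prot_atoms)
    shift_xy = np.array([center - prot_span / 2.0, center - 4.0])
    for (name, elem, rid, rname, xyz) in prot_atoms:
        anchor[(rid, name)] = len(names)
        names.append(name)
        elements.append(elem)
        resids.append(rid)
        resnames.append(rname)
        segids.append("PROT")
        coords.append((xyz[0] + shift_xy[0], xyz[1] + shift_xy[1], xyz[2]))
    bonds += prot_bonds
    n_prot = len(names)
    protein_ids = np.arange(n_prot)
    omega1_ids = np.array([i for i in range(n_prot)
                           if resids[i] in OMEGA1_RESIDS])

    lipid_atom_ids: dict = {}
    lipid_order: dict = {"upper": [], "lower": []}
    resid = 1000
    for leaflet, sign in (("upper", 1), ("lower", -1)):
        for rank, (x, y) in enumerate(slots):
            resid += 1
            latoms, lbonds = _lipid_atoms(spec, resid, "MEMB", sign, x, y)
            offset = len(names)
            amap = {}
            for (nm, el, xyz) in latoms:
                amap[nm] = len(names)
                names.append(nm)
                elements.append(el)
                resids.append(resid)
                resnames.append(spec.lipid_resname)
                segids.append("MEMB")
                coords.append(xyz)
            bonds += [(offset + i, offset + j) for i, j in lbonds]
            lipid_atom_ids[(leaflet, rank)] = amap
            lipid_order[leaflet].append(rank)

    topology = [AtomRecord(atom_id=i, name=names[i], element=elements[i],
                           residue_id=resids[i], residue_name=resnames[i],
                           segment_id=segids[i])
                for i in range(len(names))]
    topology = assign_roles(topology, bonds)
    base = np.array(coords, dtype=float)

    # lift the protein so the bound-pose min heavy-atom gap to the
    # bilayer equals BOUND_MIN_DISTANCE
    heavy_prot = np.array([i for i in protein_ids
                           if topology[i].element != "H"])
    heavy_memb = np.array([i for i in range(len(names))
                           if segids[i] == "MEMB"
                           and topology[i].element != "H"])

    def min_gap(dz):
        pc = base[heavy_prot] + (0.0, 0.0, dz)
        d = np.linalg.norm(pc[:, None, :] - base[heavy_memb][None, :, :],
                           axis=-1)
        return d.min()

    lo, hi = 0.0, 80.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_gap(mid + spec.z0) < BOUND_MIN_DISTANCE:
            lo = mid
        else:
            hi = mid
    base[protein_ids, 2] += spec.z0 + hi

    return _Scenario(topology=topology, bonds=bonds, base=base, box=box,
                     protein_ids=protein_ids, omega1_ids=omega1_ids,
                     lipid_atom_ids=lipid_atom_ids, lipid_order=lipid_order,
                     anchor=anchor)


# --------------------------------------------------------------------------
# Event realization
# --------------------------------------------------------------------------


def _perp_unit(u):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    w = np.cross(u, ref)
    return w / np.linalg.norm(w)


def _pick_lipid(sc: _Scenario, ev: ScenarioEvent, used: set) -> tuple:
    leaflet = ev.param("leaflet", "upper")
    rank = ev.param("lipid_rank")
    if rank is None:
        for r in sc.lipid_order[leaflet]:
            if (leaflet, r) not in used:
                rank = r
                break
    key = (leaflet, rank)
    if key not in sc.lipid_atom_ids:
        raise ScenarioError(f"no lipid at {key}")
    used.add(key)
    return key


def _controlled_atoms(sc: _Scenario, ev: ScenarioEvent, key) -> tuple:
    amap = sc.lipid_atom_ids[key] if key else {}
    if ev.kind == "binding":
        return tuple(sc.protein_ids)
    if ev.kind == "gate_open":
        return tuple(sc.omega1_ids)
    if ev.kind in ("hbond_on", "hbond_off"):
        return (amap["O21"],)
    if ev.kind in ("contact_on", "contact_off"):
        return (amap["C25"],)
    if ev.kind == "snorkel":
        tail = ev.param("tail", "sn1")
        return (amap[_terminal_name(sc, key, tail)],)
    if ev.kind == "tail_insertion":
        return tuple(amap[nm] for nm in amap if nm.startswith("C2")
                     and nm not in ("C2",) and len(nm) > 2)
    raise AssertionError(ev.kind)


def _terminal_name(sc: _Scenario, key, tail: str) -> str:
    prefix = "C3" if tail == "sn1" else "C2"
    names = [nm for nm in sc.lipid_atom_ids[key]
             if nm.startswith(prefix) and len(nm) > 2]
    return max(names, key=lambda nm: int(nm[2:]))


def build_scenario(spec: ScenarioSpec):
    """Build all replicas plus the shared ground-truth event log.

    Replicas share the scripted geometry and differ only in the
    positional-noise stream (seeded ``seed + replica_index``).
    """
    sc = _assemble(spec)
    n_atoms = sc.base.shape[0]
    n_frames = spec.n_frames

    has_binding = any(ev.kind == "binding" for ev in spec.events)
    used_lipids: set = set()
    plans = []       # (event, lipid_key or None)
    for ev in spec.events:
        key = None
        if ev.kind in ("hbond_on", "hbond_off", "contact_on",
                       "contact_off", "snorkel", "tail_insertion"):
            key = _pick_lipid(sc, ev, used_lipids)
        plans.append((ev, key))

    # conflict check: same atoms, overlapping scheduled windows
    controlled = [(ev, set(_controlled_atoms(sc, ev, key)))
                  for ev, key in plans]
    for i in range(len(controlled)):
        for j in range(i + 1, len(controlled)):
            (e1, a1), (e2, a2) = controlled[i], controlled[j]
            if a1 & a2 and not (
                    e1.window.end_frame < e2.window.start_frame
                    or e2.window.end_frame < e1.window.start_frame):
                raise ScenarioError(
                    f"conflicting events {e1.kind}/{e2.kind} share atoms "
                    f"in overlapping windows")

    def presence(ev: ScenarioEvent) -> FrameWindow | None:
        if ev.kind.endswith("_off"):
            if ev.window.start_frame == 0:
                return None       # switched off from the start
            return FrameWindow(0, ev.window.start_frame - 1)
        return ev.window

    kind_order = {k: i for i, k in enumerate(EVENT_KINDS)}
    ordered = sorted(plans, key=lambda p: kind_order[p[0].kind])

    def scaffold_coords(f: int) -> np.ndarray:
        """Base + scripted scaffold motion (binding, gate, snorkel,
        tail insertion); interaction placements are applied after
        noise, see ``place_interactions``."""
        c = sc.base.copy()
        if not has_binding:
            # no binding scheduled: the protein stays in solution so an
            # event-free scenario yields no protein-lipid interactions
            c[sc.protein_ids, 2] += UNBOUND_LIFT
        else:
            for ev, _ in ordered:
                if ev.kind != "binding":
                    continue
                a, b = ev.window.start_frame, ev.window.end_frame
                if f < a:
                    c[sc.protein_ids, 2] += UNBOUND_LIFT
                elif f <= b:
                    frac = (b - f) / max(b - a, 1)
                    c[sc.protein_ids, 2] += UNBOUND_LIFT * frac
        for ev, key in ordered:
            pw = presence(ev)
            inside = pw is not None and pw.contains(f)
            if ev.kind == "gate_open":
                if ev.window.contains(f):
                    c[sc.omega1_ids, 1] -= (GATE_OPEN_D1 - GATE_CLOSED_D1)
            elif ev.kind == "snorkel":
                tail = ev.param("tail", "sn1")
                t = sc.lipid_atom_ids[key][_terminal_name(sc, key, tail)]
                if inside:
                    sign = 1.0 if key[0] == "upper" else -1.0
                    c[t, 2] = sign * (spec.z0 - SNORKEL_RISE)
            elif ev.kind == "tail_insertion":
                amap = sc.lipid_atom_ids[key]
                tilt = TAIL_TILT_INSERTED if inside else TAIL_TILT_BILAYER
                sign = 1.0 if key[0] == "upper" else -1.0
                th = math.radians(tilt)
                d = np.array([math.sin(th), 0.0, sign * math.cos(th)])
                c2 = c[amap["C2"]]
                chain = sorted((nm for nm in amap if nm.startswith("C2")
                                and len(nm) > 2), key=lambda nm: int(nm[2:]))
                for k, nm in enumerate(chain, start=1):
                    c[amap[nm]] = c2 + 1.5 * k * d
        return c

    def place_interactions(c: np.ndarray, f: int, rng=None) -> np.ndarray:
        """Realize planted hydrogen bonds / hydrophobic contacts
        relative to the (possibly noised) anchor positions.

        A formed interaction constrains the partner atom, so its
        placement follows the anchors; only an attenuated residual
        jitter (0.25 sigma) is applied to it.
        """
        for ev, key in ordered:
            pw = presence(ev)
            if pw is None or not pw.contains(f):
                continue
            if ev.kind in ("hbond_on", "hbond_off"):
                o = sc.lipid_atom_ids[key]["O21"]
                d = c[sc.anchor[(476, "OG")]]
                h = c[sc.anchor[(476, "HG1")]]
                u = (h - d) / np.linalg.norm(h - d)
                w = _perp_unit(u)
                theta = math.radians(180.0 - HBOND_ANGLE)
                c[o] = h + HBOND_HA * (math.cos(theta) * u
                                       + math.sin(theta) * w)
                if rng is not None and spec.noise_sigma > 0:
                    c[o] += rng.normal(0.0, 0.25 * spec.noise_sigma, 3)
            elif ev.kind in ("contact_on", "contact_off"):
                t = sc.lipid_atom_ids[key]["C25"]
                target = c[sc.anchor[(580, "CB")]]
                c[t] = target + np.array([0.0, CONTACT_DISTANCE, 0.0])
                if rng is not None and spec.noise_sigma > 0:
                    c[t] += rng.normal(0.0, 0.25 * spec.noise_sigma, 3)
        return c

    noiseless = np.stack([place_interactions(scaffold_coords(f), f)
                          for f in range(n_frames)])

    # ground truth
    log = EventLog(scenario_id=f"seed{spec.seed}")
    heavy_prot = np.array([i for i in sc.protein_ids
                           if sc.topology[i].element != "H"])
    heavy_memb = np.array([i for i in range(n_atoms)
                           if sc.topology[i].segment_id == "MEMB"
                           and sc.topology[i].element != "H"])
    for ev, key in plans:
        if ev.kind == "binding":
            dmin = np.array([
                np.linalg.norm(
                    noiseless[f][heavy_prot][:, None, :]
                    - noiseless[f][heavy_memb][None, :, :], axis=-1).min()
                for f in range(n_frames)])
            above = np.nonzero(dmin > BINDING_CONTACT_CUTOFF)[0]
            start = int(above[-1]) + 1 if above.size else 0
            if start >= n_frames:
                raise ScenarioError("binding never completes")
            pw = FrameWindow(start, n_frames - 1)
            atoms = tuple(int(i) for i in heavy_prot)
        else:
            pw = presence(ev)
            if pw is None:
                continue
            atoms = tuple(int(i)
                          for i in _controlled_atoms(sc, ev, key))
            if ev.kind in ("hbond_on", "hbond_off"):
                atoms = (sc.anchor[(476, "OG")], sc.anchor[(476, "HG1")],
                         atoms[0])
            elif ev.kind in ("contact_on", "contact_off"):
                atoms = (sc.anchor[(580, "CB")], atoms[0])
        log.records.append(EventRecord(kind=ev.kind, atom_ids=atoms,
                                       window=ev.window, present_window=pw))

    replicas = []
    for r in range(spec.n_replicas):
        rng = np.random.default_rng(spec.seed + r)
        frames = []
        for f in range(n_frames):
            if spec.noise_sigma > 0:
                c = scaffold_coords(f) + rng.normal(
                    0.0, spec.noise_sigma, size=(n_atoms, 3))
                c = place_interactions(c, f, rng)
            else:
                c = noiseless[f]
            frames.append(Frame(c, sc.box, f * spec.frame_interval))
        replicas.append(Trajectory(sc.topology, list(sc.bonds), frames,
                                   spec.frame_interval))
    return ReplicaSet(label=log.scenario_id, replicas=replicas), log


def build_bilayer_slab(spec: ScenarioSpec) -> Trajectory:
    """Bilayer-only trajectory (no protein, no events): two leaflets on
    a rectangular grid, phosphorus planes at +/-z0 before noise."""
    slots, box_xy = _grid_positions(spec)
    box = (box_xy, box_xy, 2.0 * (spec.z0 + 55.0))
    names, elements, resids, resnames, segids = [], [], [], [], []
    coords, bonds = [], []
    resid = 0
    for leaflet, sign in (("upper", 1), ("lower", -1)):
        for (x, y) in slots:
            resid += 1
            latoms, lbonds = _lipid_atoms(spec, resid, "MEMB", sign, x, y)
            offset = len(names)
            for (nm, el, xyz) in latoms:
                names.append(nm)
                elements.append(el)
                resids.append(resid)
                resnames.append(spec.lipid_resname)
                segids.append("MEMB")
                coords.append(xyz)
            bonds += [(offset + i, offset + j) for i, j in lbonds]
    topology = assign_roles(
        [AtomRecord(atom_id=i, name=names[i], element=elements[i],
                    residue_id=resids[i], residue_name=resnames[i],
                    segment_id=segids[i]) for i in range(len(names))],
        bonds)
    base = np.array(coords, dtype=float)
    rng = np.random.default_rng(spec.seed)
    frames = []
    for f in range(spec.n_frames):
        c = base
        if spec.noise_sigma > 0:
            c = c + rng.normal(0.0, spec.noise_sigma, size=base.shape)
        frames.append(Frame(c.copy(), box, f * spec.frame_interval))
    return Trajectory(topology, bonds, frames, spec.frame_interval)


def demo_events(n_frames: int = 200) -> tuple:
    """The standard planted sequence: binding, then gate opening with a
    hydrogen bond, a hydrophobic contact, snorkeling lipids under the
    gate (three upper-leaflet, one lower-leaflet baseline), and one
    tail insertion. Windows scale with ``n_frames``."""

    def fr(x):
        return max(0, min(n_frames - 1, int(round(x * n_frames))))

    return (
        _event("binding", fr(0.10), fr(0.25)),
        _event("gate_open", fr(0.40), fr(0.70)),
        _event("hbond_on", fr(0.45), fr(0.65)),
        _event("contact_on", fr(0.47), fr(0.68)),
        _event("snorkel", fr(0.50), fr(0.80), lipid_rank=2),
        _event("snorkel", fr(0.52), fr(0.82), lipid_rank=3),
        _event("snorkel", fr(0.54), fr(0.84), lipid_rank=4),
        _event("snorkel", fr(0.50), fr(0.80), leaflet="lower",
               lipid_rank=0),
        _event("tail_insertion", fr(0.55), n_frames - 1, lipid_rank=5),
    )


def write_scenario(replica_set: ReplicaSet, log: EventLog, outdir) -> dict:
    """Write PDB topology, plain-text frames per replica, and the JSON
    event log; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj0 = replica_set.replicas[0]
    top_path = outdir / "topology.pdb"
    write_pdb(traj0.topology, traj0.frames[0].coords, top_path,
              box=traj0.frames[0].box)
    frame_paths = []
    for i, rep in enumerate(replica_set.replicas):
        p = outdir / f"replica{i}.frames"
        write_text_frames(rep, p)
        frame_paths.append(str(p))
    log_path = outdir / "events.json"
    log.to_json(log_path)
    return {"topology": str(top_path), "frames": frame_paths,
            "events": str(log_path)}
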