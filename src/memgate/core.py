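"""Domain types, topology/trajectory ingestion and atom selection.

Conventions used throughout the package:

* distances in Å, times in ns, angles in degrees, masses in Da;
* frame indices are 0-based and all frame windows are inclusive on both
  ends;
* the membrane normal is +z and trajectories are assumed to be aligned
  that way (slab geometry), with periodic images applied in x/y only.

Binary formats (PDB/PSF topologies, DCD/XTC trajectories) are read
through MDAnalysis; in addition the package defines a human-readable
plain-text frame format so synthetic fixtures can live in version
control (see :func:`read_text_frames`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "ReplicaSet",
    "FrameWindow",
    "TopologyError",
    "FormatError",
    "SelectionError",
    "load_trajectory",
    "read_text_frames",
    "write_text_frames",
    "write_pdb",
    "select",
    "assign_roles",
    "infer_bonds",
    "aromatic_rings",
    "load_role_overrides",
]

# --------------------------------------------------------------------------
# Reference tables
# --------------------------------------------------------------------------

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}

LIPID_RESNAMES = {
    "POPC", "POPE", "POPS", "POPI", "POPA", "DOPC", "DPPC", "DOPE",
    "CHL1", "CER1", "CER160", "PSM", "SAPI", "TOYL",
}

ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
}

ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16,
    "NA": 11, "CL": 17, "K": 19, "MG": 12,
}

# single-bond covalent radii (Å); inference cutoff = r_i + r_j + 0.4 Å
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "P": 1.07, "S": 1.05,
}
BOND_FUDGE = 0.4

# aromatic ring atom names per residue type (6-rings used for cation-pi)
AROMATIC_RING_ATOMS = {
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
}

KNOWN_FLAGS = {
    "hydrophobic_candidate", "hbond_donor_heavy", "hbond_hydrogen",
    "hbond_acceptor", "aromatic_ring_member", "choline_nitrogen",
    "phosphorus", "tail_terminal_carbon", "c2_carbon", "beta_carbon",
    "alpha_carbon", "backbone",
}

_TAIL_CARBON_RE = re.compile(r"^C([23])(\d+)$")


class TopologyError(ValueError):
    """Raised when a topology is inconsistent with an analysis request."""


class FormatError(ValueError):
    """Raised for unreadable or mismatched input files."""


class SelectionError(ValueError):
    """Raised for malformed selection expressions; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology.

    ``flags`` holds role labels (e.g. ``phosphorus``,
    ``hbond_donor_heavy``) used by the detectors; see
    :func:`assign_roles`.
    """

    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    segment_id: str
    mass: float = 0.0
    flags: frozenset = frozenset()

    @property
    def residue_key(self) -> str:
        return f"{self.segment_id}/{self.residue_name}{self.residue_id}"


@dataclass
class Frame:
    """Coordinates (N, 3) in Å, orthorhombic box lengths in Å, time in ns."""

    coords: np.ndarray
    box: tuple
    time: float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")


@dataclass
class Trajectory:
    topology: list
    bonds: list
    frames: list
    frame_interval: float = 1.0

    def __post_init__(self):
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise FormatError(
                    f"frame {i} has {fr.coords.shape[0]} atoms, "
                    f"topology has {n}"
                )
        times = [fr.time for fr in self.frames]
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > 1e-6):
                raise ValueError("frame spacing must be constant")
            self.frame_interval = float(dt[0])

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([fr.coords for fr in self.frames])

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def bonded_neighbors(self) -> dict:
        nb: dict = {a.atom_id: set() for a in self.topology}
        for i, j in self.bonds:
            nb[i].add(j)
            nb[j].add(i)
        return nb

    def with_stride(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(
            self.topology, self.bonds, self.frames[::stride],
            self.frame_interval * stride,
        )


@dataclass
class ReplicaSet:
    """Independent replicas of one system, sharing a residue naming scheme."""

    label: str
    replicas: list

    def __post_init__(self):
        if not self.replicas:
            raise ValueError("ReplicaSet needs at least one replica")
        ref = [(a.residue_id, a.residue_name, a.name)
               for a in self.replicas[0].topology]
        for k, rep in enumerate(self.replicas[1:], start=1):
            cur = [(a.residue_id, a.residue_name, a.name)
                   for a in rep.topology]
            if cur != ref:
                raise TopologyError(
                    f"replica {k} residue/atom naming differs from replica 0"
                )


@dataclass(frozen=True)
class FrameWindow:
    """Inclusive 0-based frame range [start_frame, end_frame]."""

    start_frame: int
    end_frame: int

    def __post_init__(self):
        if not (0 <= self.start_frame <= self.end_frame):
            raise ValueError(
                f"invalid window [{self.start_frame}, {self.end_frame}]"
            )

    def __len__(self) -> int:
        return self.end_frame - self.start_frame + 1

    def frames(self) -> range:
        return range(self.start_frame, self.end_frame + 1)

    def contains(self, frame: int) -> bool:
        return self.start_frame <= frame <= self.end_frame

    def clipped(self, n_frames: int) -> "FrameWindow":
        if self.start_frame >= n_frames:
            raise ValueError("window starts beyond trajectory end")
        return FrameWindow(self.start_frame,
                           min(self.end_frame, n_frames - 1))


# --------------------------------------------------------------------------
# Role assignment
# --------------------------------------------------------------------------


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    for two in ("CL", "NA", "MG"):
        if stripped.upper().startswith(two):
            return two
    head = stripped.lstrip("0123456789")
    return head[0].upper() if head else ""


def is_protein_atom(atom: AtomRecord) -> bool:
    return atom.residue_name in AMINO_ACIDS


def is_lipid_atom(atom: AtomRecord) -> bool:
    return atom.residue_name in LIPID_RESNAMES


def assign_roles(topology: Sequence[AtomRecord],
                 bonds: Iterable,
                 overrides: dict | None = None) -> list:
    """Return a topology with role flags filled in.

    Heuristics:

    * ``phosphorus``: element P;
    * ``choline_nitrogen``: lipid N bonded to >= 3 carbons;
    * ``hydrophobic_candidate``: C bonded to no N/O/S/P, plus the S of
      Cys/Met (overridable per atom name via ``overrides``);
    * ``hbond_donor_heavy`` / ``hbond_hydrogen``: N/O/S with bonded H and
      that H;
    * ``hbond_acceptor``: any N or O;
    * ``aromatic_ring_member``: named ring atoms of Trp/Phe/Tyr;
    * ``c2_carbon`` / ``tail_terminal_carbon``: glycerol C2 and the
      highest-numbered carbon of each acyl tail (CHARMM ``C2x``/``C3x``
      naming, e.g. C218/C316);
    * ``backbone`` / ``alpha_carbon`` / ``beta_carbon``: protein N, CA,
      C, O / CA / CB.

    ``overrides`` maps ``(residue_name, atom_name)`` to a set of flags
    replacing the heuristic set for matching atoms.
    """
    nb: dict = {a.atom_id: set() for a in topology}
    for i, j in bonds:
        nb[i].add(j)
        nb[j].add(i)
    by_id = {a.atom_id: a for a in topology}

    # terminal tail carbon: highest position per (residue, tail) chain
    tail_max: dict = {}
    for a in topology:
        m = _TAIL_CARBON_RE.match(a.name)
        if m and is_lipid_atom(a) and int(m.group(2)) >= 2:
            key = (a.segment_id, a.residue_id, m.group(1))
            if key not in tail_max or int(m.group(2)) > tail_max[key][0]:
                tail_max[key] = (int(m.group(2)), a.atom_id)
    terminal_ids = {v[1] for v in tail_max.values()}

    out = []
    for a in topology:
        elem = a.element or _guess_element(a.name)
        flags = set()
        neighbors = [by_id[i] for i in nb[a.atom_id]]
        nel = [x.element or _guess_element(x.name) for x in neighbors]
        if elem == "P":
            flags.add("phosphorus")
        if elem == "N" and is_lipid_atom(a) and nel.count("C") >= 3:
            flags.add("choline_nitrogen")
        if elem == "C" and not any(e in ("N", "O", "S", "P") for e in nel):
            flags.add("hydrophobic_candidate")
        if elem == "S" and a.residue_name in ("CYS", "MET"):
            flags.add("hydrophobic_candidate")
        if elem in ("N", "O", "S") and "H" in nel:
            flags.add("hbond_donor_heavy")
        if elem == "H" and any(e in ("N", "O", "S") for e in nel):
            flags.add("hbond_hydrogen")
        if elem in ("N", "O"):
            flags.add("hbond_acceptor")
        ring = AROMATIC_RING_ATOMS.get(a.residue_name, ())
        if a.name in ring:
            flags.add("aromatic_ring_member")
        if a.atom_id in terminal_ids:
            flags.add("tail_terminal_carbon")
        if a.name == "C2" and is_lipid_atom(a):
            flags.add("c2_carbon")
        if is_protein_atom(a):
            if a.name in ("N", "CA", "C", "O"):
                flags.add("backbone")
            if a.name == "CA":
                flags.add("alpha_carbon")
            if a.name == "CB":
                flags.add("beta_carbon")
        if overrides and (a.residue_name, a.name) in overrides:
            flags = set(overrides[(a.residue_name, a.name)])
        unknown = flags - KNOWN_FLAGS
        if unknown:
            raise TopologyError(f"unknown flags {unknown} for atom {a.name}")
        mass = a.mass if a.mass > 0 else ELEMENT_MASSES.get(elem, 0.0)
        out.append(replace(a, element=elem, mass=mass,
                           flags=frozenset(flags)))
    return out


def infer_bonds(topology: Sequence[AtomRecord],
                coords: np.ndarray) -> list:
    """Distance-based bond inference (covalent radii + 0.4 Å fudge).

    Fallback for topologies without explicit bonds (e.g. bare PDB); only
    intra-residue pairs are considered plus peptide/phosphodiester-style
    links between consecutive residues of the same segment.
    """
    coords = np.asarray(coords, dtype=float)
    bonds = []
    by_res: dict = {}
    for a in topology:
        by_res.setdefault((a.segment_id, a.residue_id), []).append(a)

    def try_pair(a, b):
        ra = COVALENT_RADII.get(a.element or _guess_element(a.name))
        rb = COVALENT_RADII.get(b.element or _guess_element(b.name))
        if ra is None or rb is None:
            return
        d = np.linalg.norm(coords[a.atom_id] - coords[b.atom_id])
        if d <= ra + rb + BOND_FUDGE:
            bonds.append((a.atom_id, b.atom_id))

    keys = sorted(by_res)
    for key in keys:
        atoms = by_res[key]
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                try_pair(atoms[i], atoms[j])
    for (seg, rid) in keys:
        nxt = (seg, rid + 1)
        if nxt in by_res:
            for a in by_res[(seg, rid)]:
                for b in by_res[nxt]:
                    try_pair(a, b)
    return bonds


def load_role_overrides(path) -> dict:
    """Load an atom-role assignment table from YAML.

    Layout: ``{residue_name: {atom_name: [flag, ...]}}``. The returned
    mapping plugs into :func:`assign_roles` / :func:`load_trajectory`
    (``role_overrides``) and replaces the heuristic flag set for the
    listed atoms — e.g. to reproduce a bespoke hydrophobic-candidate
    table.
    """
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    overrides = {}
    for resname, atoms in data.items():
        if not isinstance(atoms, dict):
            raise FormatError(
                f"role table: {resname!r} must map atom names to flags")
        for atom_name, flags in atoms.items():
            flags = set(flags or ())
            unknown = flags - KNOWN_FLAGS
            if unknown:
                raise FormatError(
                    f"role table: unknown flag(s) {sorted(unknown)} "
                    f"for {resname}/{atom_name}")
            overrides[(str(resname), str(atom_name))] = frozenset(flags)
    return overrides


def aromatic_rings(topology: Sequence[AtomRecord]) -> list:
    """Group ``aromatic_ring_member`` atoms into per-residue ring id-lists."""
    rings: dict = {}
    for a in topology:
        if "aromatic_ring_member" in a.flags:
            rings.setdefault((a.segment_id, a.residue_id), []).append(
                a.atom_id)
    return [sorted(v) for _, v in sorted(rings.items())]


# --------------------------------------------------------------------------
# Plain-text frame format
# --------------------------------------------------------------------------
#
#   NATOMS <N>
#   FRAME <time_ns> <Lx> <Ly> <Lz>
#   <atom_id> <x> <y> <z>        (N lines, Å, 6 decimals)
#   FRAME ...


def write_text_frames(traj: Trajectory, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"NATOMS {traj.n_atoms}\n")
        for fr in traj.frames:
            bx = " ".join(f"{b:.6f}" for b in fr.box)
            fh.write(f"FRAME {fr.time:.6f} {bx}\n")
            for i, (x, y, z) in enumerate(fr.coords):
                fh.write(f"{i} {x:.6f} {y:.6f} {z:.6f}\n")


def read_text_frames(path) -> list:
    path = Path(path)
    frames = []
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 2 or header[0] != "NATOMS":
            raise FormatError(f"{path}: expected 'NATOMS <N>' header")
        n = int(header[1])
        while True:
            line = fh.readline()
            if not line:
                break
            parts = line.split()
            if parts[0] != "FRAME" or len(parts) != 5:
                raise FormatError(f"{path}: malformed FRAME line: {line!r}")
            time = float(parts[1])
            box = tuple(float(v) for v in parts[2:5])
            coords = np.empty((n, 3))
            for k in range(n):
                row = fh.readline().split()
                if len(row) != 4:
                    raise FormatError(
                        f"{path}: truncated frame at t={time}")
                coords[int(row[0])] = [float(v) for v in row[1:]]
            frames.append(Frame(coords, box, time))
    return frames


def write_pdb(topology: Sequence[AtomRecord], coords: np.ndarray,
              path, box=None) -> None:
    """Minimal PDB writer for synthetic topologies (ATOM records + CRYST1)."""
    coords = np.asarray(coords, dtype=float)
    with Path(path).open("w") as fh:
        if box is not None:
            fh.write(
                f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                f"  90.00  90.00  90.00 P 1           1\n")
        for a in topology:
            x, y, z = coords[a.atom_id]
            name = a.name if len(a.name) >= 4 else f" {a.name}"
            fh.write(
                "ATOM  {serial:>5d} {name:<4s} {res:<4s}{chain}{rid:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}      "
                "{seg:<4s}{elem:>2s}\n".format(
                    serial=(a.atom_id + 1) % 100000, name=name[:4],
                    res=a.residue_name[:4], chain="A",
                    rid=a.residue_id % 10000, x=x, y=y, z=z, occ=1.0, b=0.0,
                    seg=a.segment_id[:4], elem=(a.element or "")[:2]))
        fh.write("END\n")


# --------------------------------------------------------------------------
# Loading
# --------------------------------------------------------------------------

_TEXT_SUFFIXES = {".frames", ".txt"}


def _topology_from_mda(universe) -> tuple:
    atoms = []
    for i, at in enumerate(universe.atoms):
        try:
            elem = at.element.upper()
        except Exception:
            elem = _guess_element(at.name)
        try:
            seg = at.segid.strip() or "SYS"
        except Exception:
            seg = "SYS"
        try:
            mass = float(at.mass)
        except Exception:
            mass = 0.0
        atoms.append(AtomRecord(
            atom_id=i, name=at.name, element=elem,
            residue_id=int(at.resid), residue_name=at.resname.strip(),
            segment_id=seg, mass=mass))
    bonds = []
    if hasattr(universe, "bonds"):
        try:
            bonds = [(int(b.atoms[0].index), int(b.atoms[1].index))
                     for b in universe.bonds]
        except Exception:
            bonds = []
    return atoms, bonds


def load_trajectory(topology_path, trajectory_path=None, *,
                    frame_interval: float = 1.0,
                    stride: int = 1,
                    role_overrides: dict | None = None) -> Trajectory:
    """Load topology + frames into a :class:`Trajectory`.

    ``topology_path`` may be PDB or PSF; ``trajectory_path`` may be DCD,
    XTC, a package plain-text ``.frames``/``.txt`` file, or omitted when
    the PDB itself carries the (single) frame. Bonds come from the
    topology when present, otherwise from covalent-radius inference.
    ``frame_interval`` (ns) is used when the trajectory format does not
    store times.
    """
    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FormatError(f"topology not found: {topology_path}")

    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda

        if (trajectory_path is not None
                and Path(trajectory_path).suffix in _TEXT_SUFFIXES):
            u = mda.Universe(str(topology_path))
            topology, bonds = _topology_from_mda(u)
            frames = read_text_frames(trajectory_path)
            if frames and frames[0].coords.shape[0] != len(topology):
                raise FormatError(
                    f"atom-count mismatch: topology has {len(topology)} "
                    f"atoms, frames have {frames[0].coords.shape[0]}")
        else:
            if trajectory_path is None:
                u = mda.Universe(str(topology_path))
            else:
                if not Path(trajectory_path).exists():
                    raise FormatError(
                        f"trajectory not found: {trajectory_path}")
                try:
                    u = mda.Universe(str(topology_path),
                                     str(trajectory_path))
                except Exception as exc:
                    msg = str(exc)
                    if "same number of atom" in msg or "atoms" in msg:
                        raise FormatError(
                            f"atom-count mismatch between topology and "
                            f"trajectory: {msg}") from exc
                    raise FormatError(f"unreadable trajectory: {msg}") \
                        from exc
            topology, bonds = _topology_from_mda(u)
            frames = []
            for ts in u.trajectory:
                if ts.dimensions is not None and ts.dimensions[0] > 0:
                    box = tuple(float(v) for v in ts.dimensions[:3])
                else:
                    span = ts.positions.max(0) - ts.positions.min(0) + 20.0
                    box = tuple(float(v) for v in span)
                t = float(ts.time) / 1000.0  # MDAnalysis ps -> ns
                frames.append(Frame(ts.positions.astype(float), box, t))
            times = [fr.time for fr in frames]
            if len(times) > 1 and abs(times[1] - times[0]) < 1e-12:
                for k, fr in enumerate(frames):
                    fr.time = k * frame_interval

    if not bonds:
        if frames:
            bonds = infer_bonds(topology, frames[0].coords)
    topology = assign_roles(topology, bonds, overrides=role_overrides)
    traj = Trajectory(topology, bonds, frames)
    if stride > 1:
        traj = traj.with_stride(stride)
    return traj


# --------------------------------------------------------------------------
# Selection language
# --------------------------------------------------------------------------
#
# Grammar:  expr := term ('or' term)* ; term := factor ('and' factor)* ;
# factor := 'not' factor | '(' expr ')' | primitive
# primitives: name/resname/segid/element <values...>, resid <n|a-b ...>,
#             flag:<flagname>, protein, lipid, all

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or", "not", "(", ")"}
_FIELD_WORDS = {"name", "resname", "segid", "element", "resid"}


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = [(m.group(0), m.start())
                       for m in _TOKEN_RE.finditer(text)]
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else \
            (None, len(self.text))

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        if not self.tokens:
            raise SelectionError("empty selection expression", 0)
        node = self.expr()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok!r}", at)
        return node

    def expr(self):
        left = self.term()
        while self.peek()[0] == "or":
            self.take()
            left = ("or", left, self.term())
        return left

    def term(self):
        left = self.factor()
        while self.peek()[0] == "and":
            self.take()
            left = ("and", left, self.factor())
        return left

    def factor(self):
        tok, at = self.peek()
        if tok == "not":
            self.take()
            return ("not", self.factor())
        if tok == "(":
            self.take()
            node = self.expr()
            tok2, at2 = self.take()
            if tok2 != ")":
                raise SelectionError("expected ')'", at2)
            return node
        return self.primitive()

    def primitive(self):
        tok, at = self.take()
        if tok is None:
            raise SelectionError("unexpected end of expression", at)
        if tok in ("all", "protein", "lipid"):
            return (tok,)
        if tok.startswith("flag:"):
            flag = tok[5:]
            if flag not in KNOWN_FLAGS:
                raise SelectionError(f"unknown flag {flag!r}", at)
            return ("flag", flag)
        if tok in _FIELD_WORDS:
            values = []
            while True:
                nxt, _ = self.peek()
                if nxt is None or nxt in _KEYWORDS or nxt in _FIELD_WORDS \
                        or nxt.startswith("flag:") \
                        or nxt in ("all", "protein", "lipid"):
                    break
                values.append(self.take()[0])
            if not values:
                raise SelectionError(f"{tok!r} needs at least one value", at)
            if tok == "resid":
                ranges = []
                for v in values:
                    m = re.fullmatch(r"(-?\d+)(?:[-:](-?\d+))?", v)
                    if not m:
                        raise SelectionError(
                            f"bad resid value {v!r}", at)
                    lo = int(m.group(1))
                    hi = int(m.group(2)) if m.group(2) else lo
                    ranges.append((lo, hi))
                return ("resid", ranges)
            return (tok, values)
        raise SelectionError(f"unknown keyword {tok!r}", at)


def _eval_node(node, atom: AtomRecord) -> bool:
    op = node[0]
    if op == "or":
        return _eval_node(node[1], atom) or _eval_node(node[2], atom)
    if op == "and":
        return _eval_node(node[1], atom) and _eval_node(node[2], atom)
    if op == "not":
        return not _eval_node(node[1], atom)
    if op == "all":
        return True
    if op == "protein":
        return is_protein_atom(atom)
    if op == "lipid":
        return is_lipid_atom(atom)
    if op == "flag":
        return node[1] in atom.flags
    if op == "name":
        return atom.name in node[1]
    if op == "resname":
        return atom.residue_name in node[1]
    if op == "segid":
        return atom.segment_id in node[1]
    if op == "element":
        return atom.element in node[1]
    if op == "resid":
        return any(lo <= atom.residue_id <= hi for lo, hi in node[1])
    raise AssertionError(op)


def select(traj: Trajectory, expression: str) -> list:
    """Evaluate a selection expression; returns a sorted atom-id list.

    Examples: ``"flag:phosphorus"``, ``"resname TRP and name CA"``,
    ``"segid PROT and resid 470-480"``, ``"lipid and not element H"``.
    """
    tree = _Parser(expression).parse()
    return sorted(a.atom_id for a in traj.topology if _eval_node(tree, a))
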