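"""Shared fixtures: tiny random systems and independent brute-force
detectors used as oracles against the vectorized implementations."""

import math

import numpy as np
import pytest

from memgate.core import AtomRecord, Frame, FrameWindow, Trajectory


def make_atoms(spec_list):
    """Build AtomRecords from (name, element, resid, resname, segid,
    flags) tuples."""
    atoms = []
    for i, (name, elem, rid, rname, seg, flags) in enumerate(spec_list):
        atoms.append(AtomRecord(
            atom_id=i, name=name, element=elem, residue_id=rid,
            residue_name=rname, segment_id=seg, mass=12.0,
            flags=frozenset(flags)))
    return atoms


def make_traj(atoms, coords_per_frame, box=(50.0, 50.0, 100.0),
              bonds=(), frame_interval=1.0):
    frames = [Frame(np.asarray(c, dtype=float), box, k * frame_interval)
              for k, c in enumerate(coords_per_frame)]
    return Trajectory(list(atoms), list(bonds), frames, frame_interval)


def random_system(rng, n_atoms=60, n_frames=30, box=(30.0, 30.0, 60.0),
                  spread=12.0):
    """Random toy trajectory: all atoms are hydrophobic candidates in
    distinct residues, so every cross pair is eligible."""
    atoms = make_atoms([
        (f"C{i}", "C", i, "LIG", "SYS", {"hydrophobic_candidate"})
        for i in range(n_atoms)])
    coords = rng.uniform(0.0, spread, size=(n_frames, n_atoms, 3))
    coords[..., 2] += 10.0
    return make_traj(atoms, coords, box=box)


# ---------------------------------------------------------------------
# Brute-force oracles (python loops, no shared code with the package)
# ---------------------------------------------------------------------


def mi_dist(p, q, box):
    dx = p[0] - q[0]
    dy = p[1] - q[1]
    dz = p[2] - q[2]
    dx -= box[0] * round(dx / box[0])
    dy -= box[1] * round(dy / box[1])
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def runs_of(flags):
    """Maximal runs of truthy values as inclusive (start, end)."""
    out = []
    start = None
    for k, v in enumerate(flags):
        if v and start is None:
            start = k
        elif not v and start is not None:
            out.append((start, k - 1))
            start = None
    if start is not None:
        out.append((start, len(flags) - 1))
    return out


def brute_hydrophobic(traj, candidates, cutoff, min_consecutive,
                      excluded):
    """Frame-by-frame pairwise detector + run-length filter."""
    events = []
    res = {a.atom_id: (a.segment_id, a.residue_id) for a in traj.topology}
    cands = sorted(candidates)
    for x in range(len(cands)):
        for y in range(x + 1, len(cands)):
            i, j = cands[x], cands[y]
            if res[i] == res[j] or (i, j) in excluded:
                continue
            flags = []
            for fr in traj.frames:
                d = mi_dist(fr.coords[i], fr.coords[j], fr.box)
                flags.append(d <= cutoff + 1e-9)
            for a, b in runs_of(flags):
                if b - a + 1 >= min_consecutive:
                    events.append((i, j, a, b))
    return sorted(events)


def brute_hbonds(traj, triples, d_ha, angle_min, min_consecutive):
    events = []
    for (d, h, a) in triples:
        flags = []
        for fr in traj.frames:
            dist = mi_dist(fr.coords[h], fr.coords[a], fr.box)
            v1 = fr.coords[d] - fr.coords[h]
            v2 = fr.coords[a] - fr.coords[h]
            cosang = float(np.dot(v1, v2)
                           / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            flags.append(dist <= d_ha + 1e-9 and ang >= angle_min - 1e-9)
        for lo, hi in runs_of(flags):
            if hi - lo + 1 >= min_consecutive:
                events.append((d, h, a, lo, hi))
    return sorted(events)


def brute_cation_pi(traj, rings, cations, cutoff, min_consecutive):
    events = []
    for ring in rings:
        for n in cations:
            flags = []
            for fr in traj.frames:
                dmax = max(mi_dist(fr.coords[r], fr.coords[n], fr.box)
                           for r in ring)
                flags.append(dmax < cutoff)
            for lo, hi in runs_of(flags):
                if hi - lo + 1 >= min_consecutive:
                    events.append((tuple(ring), n, lo, hi))
    return sorted(events)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def bound_scenario():
    """One noiseless demo scenario with the full planted sequence
    (session-scoped: it is deterministic and read-only)."""
    from memgate.synth import ScenarioSpec, build_scenario, demo_events
    spec = ScenarioSpec(seed=7, n_replicas=2, events=demo_events(200))
    return build_scenario(spec)


@pytest.fixture(scope="session")
def bound_bundle(tmp_path_factory, bound_scenario):
    """Full pipeline bundle for the demo scenario."""
    import memgate.cli as cli

    replica_set, event_log = bound_scenario
    config = cli.RunConfig(seed=7, outdir=str(
        tmp_path_factory.mktemp("bundle")))
    return cli.run_pipeline(config, replica_set=replica_set,
                            event_log=event_log)
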