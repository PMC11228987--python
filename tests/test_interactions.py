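"""Interaction detectors: geometric criteria, persistence rules,
replica consensus and windowed series; brute-force oracle equivalence."""

import numpy as np
import pytest

from memgate.core import FrameWindow, TopologyError
from memgate.interactions import (build_inventory, detect_cation_pi,
                                  detect_hbonds, detect_hydrophobic,
                                  replica_consensus,
                                  windowed_contact_series)

from conftest import (brute_cation_pi, brute_hbonds, brute_hydrophobic,
                      make_atoms, make_traj, random_system)


def two_carbon_traj(distances, box=(50, 50, 100)):
    """Two apolar atoms in different residues, separated along x by the
    given per-frame distances."""
    atoms = make_atoms([
        ("C1", "C", 1, "LIG", "SYS", {"hydrophobic_candidate"}),
        ("C2", "C", 2, "LIG", "SYS", {"hydrophobic_candidate"}),
    ])
    coords = [np.array([[0.0, 0.0, 10.0], [d, 0.0, 10.0]])
              for d in distances]
    return make_traj(atoms, coords, box=box)


def hbond_traj(dist, angle_deg, n_frames=5):
    """Donor-H along +x, acceptor placed at the requested H-A distance
    and D-H-A angle."""
    theta = np.radians(180.0 - angle_deg)
    a_pos = np.array([1.0, 0.0, 0.0]) + dist * np.array(
        [np.cos(theta), np.sin(theta), 0.0])
    atoms = make_atoms([
        ("OG", "O", 1, "SER", "PROT",
         {"hbond_donor_heavy", "hbond_acceptor"}),
        ("HG1", "H", 1, "SER", "PROT", {"hbond_hydrogen"}),
        ("O21", "O", 2, "TOYL", "MEMB", {"hbond_acceptor"}),
    ])
    coords = [np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], a_pos])
              for _ in range(n_frames)]
    return make_traj(atoms, coords, bonds=[(0, 1)])


class TestHydrophobic:
    def test_event_window_matches_construction(self):
        d = [8.0] * 10 + [2.8] * 11 + [8.0] * 9
        events = detect_hydrophobic(two_carbon_traj(d), cutoff=3.0)
        assert len(events) == 1
        assert events[0].window == FrameWindow(10, 20)
        assert events[0].kind == "hydrophobic"

    def test_single_frame_contact_rejected(self):
        d = [8.0] * 10 + [2.8] + [8.0] * 9
        assert detect_hydrophobic(two_carbon_traj(d)) == []

    def test_min_consecutive_one_reduces_to_framewise(self):
        d = [8.0, 2.8, 8.0, 2.9, 2.9, 8.0]
        events = detect_hydrophobic(two_carbon_traj(d), min_consecutive=1)
        assert [(e.window.start_frame, e.window.end_frame)
                for e in events] == [(1, 1), (3, 4)]

    def test_bonded_and_intra_residue_pairs_excluded(self):
        atoms = make_atoms([
            ("C1", "C", 1, "LIG", "SYS", {"hydrophobic_candidate"}),
            ("C2", "C", 1, "LIG", "SYS", {"hydrophobic_candidate"}),
            ("C3", "C", 2, "LIG", "SYS", {"hydrophobic_candidate"}),
            ("C4", "C", 3, "LIG", "SYS", {"hydrophobic_candidate"}),
        ])
        coords = [np.array([[0, 0, 10], [1.5, 0, 10], [2.9, 0, 10],
                            [4.3, 0, 10.0]])] * 3
        traj = make_traj(atoms, coords, bonds=[(0, 1), (1, 2)])
        events = detect_hydrophobic(traj)
        pairs = {e.atoms for e in events}
        assert (0, 1) not in pairs       # intra-residue
        assert (1, 2) not in pairs       # bonded (1-2)
        assert (0, 2) not in pairs       # 1-3 connected
        assert (2, 3) in pairs           # eligible pair at 1.4 Å

    def test_cutoff_monotonicity(self, rng):
        traj = random_system(rng, n_atoms=30, n_frames=20)
        small = detect_hydrophobic(traj, cutoff=2.5, min_consecutive=1)
        large = detect_hydrophobic(traj, cutoff=4.0, min_consecutive=1)

        def framewise(events):
            out = set()
            for e in events:
                for f in e.window.frames():
                    out.add((e.atoms, f))
            return out

        assert framewise(small) <= framewise(large)


class TestHbonds:
    @pytest.mark.parametrize("dist,angle,accepted", [
        (1.9, 165.0, True),
        (2.4, 130.0, True),      # both criteria exactly at the boundary
        (2.41, 130.0, False),    # just beyond the distance criterion
        (2.4, 129.9, False),     # just below the angle criterion
        (1.9, 120.0, False),
        (2.5, 170.0, False),
    ])
    def test_criterion_boundaries(self, dist, angle, accepted):
        events = detect_hbonds(hbond_traj(dist, angle))
        assert bool(events) == accepted
        if accepted:
            assert events[0].window == FrameWindow(0, 4)

    def test_hydrogen_without_donor_is_topology_error(self):
        atoms = make_atoms([
            ("HG1", "H", 1, "SER", "PROT", {"hbond_hydrogen"}),
            ("O21", "O", 2, "TOYL", "MEMB", {"hbond_acceptor"}),
        ])
        traj = make_traj(atoms, [np.zeros((2, 3)) + 10.0])
        with pytest.raises(TopologyError, match="donor"):
            detect_hbonds(traj)

    def test_persistence_requires_two_frames(self):
        traj = hbond_traj(1.9, 165.0, n_frames=1)
        assert detect_hbonds(traj) == []
        assert len(detect_hbonds(traj, min_consecutive=1)) == 1


class TestCationPi:
    def _ring_traj(self, n_pos, n_frames=5, ring_radius=1.39):
        angles = np.radians(np.arange(0, 360, 60))
        ring = [(ring_radius * np.cos(a), ring_radius * np.sin(a), 0.0)
                for a in angles]
        spec = [(nm, "C", 1, "TRP", "PROT", {"aromatic_ring_member"})
                for nm in ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")]
        spec.append(("N", "N", 2, "TOYL", "MEMB", {"choline_nitrogen"}))
        atoms = make_atoms(spec)
        coords = [np.array(ring + [n_pos]) for _ in range(n_frames)]
        return make_traj(atoms, coords)

    def test_nitrogen_above_centroid_detected(self):
        events = detect_cation_pi(self._ring_traj((0.0, 0.0, 4.0)))
        assert len(events) == 1
        assert events[0].window == FrameWindow(0, 4)

    def test_one_far_ring_atom_vetoes(self):
        # N placed so five atoms are within 7 Å but one is at 7.2 Å
        ring_r = 1.39
        n_pos = (ring_r - 7.2, 0.0, 0.0)  # farthest atom at exactly 7.2
        events = detect_cation_pi(self._ring_traj(n_pos))
        assert events == []

    def test_wrong_ring_size_is_topology_error(self):
        traj = self._ring_traj((0, 0, 4.0))
        with pytest.raises(TopologyError, match="ring"):
            detect_cation_pi(traj, rings=[[0, 1, 2]])

    def test_grid_scan_matches_max_distance_rule(self, rng):
        traj = self._ring_traj((0, 0, 4.0), n_frames=1)
        ring_ids = list(range(6))
        c = traj.frames[0].coords
        for _ in range(200):
            pos = rng.uniform(-9, 9, size=3)
            c[6] = pos
            events = detect_cation_pi(traj, min_consecutive=1)
            dmax = max(np.linalg.norm(c[r] - pos) for r in ring_ids)
            assert bool(events) == (dmax < 7.0)


class TestOracleEquivalence:
    """Vectorized detectors against frame-by-frame brute force with
    run-length filtering (independent python implementation)."""

    @pytest.mark.parametrize("seed", range(6))
    def test_hydrophobic_equivalence(self, seed):
        rng = np.random.default_rng(1000 + seed)
        traj = random_system(rng, n_atoms=40, n_frames=25, spread=10.0)
        events = detect_hydrophobic(traj, cutoff=3.0, min_consecutive=2)
        got = sorted((e.atoms[0], e.atoms[1], e.window.start_frame,
                      e.window.end_frame) for e in events)
        cands = [a.atom_id for a in traj.topology]
        assert got == brute_hydrophobic(traj, cands, 3.0, 2, set())

    @pytest.mark.parametrize("seed", range(3))
    def test_hbond_equivalence(self, seed):
        rng = np.random.default_rng(2000 + seed)
        spec = []
        for r in range(6):
            spec.append((f"O{r}", "O", r, "SER", "PROT",
                         {"hbond_donor_heavy", "hbond_acceptor"}))
            spec.append((f"H{r}", "H", r, "SER", "PROT",
                         {"hbond_hydrogen"}))
        atoms = make_atoms(spec)
        bonds = [(2 * r, 2 * r + 1) for r in range(6)]
        coords = rng.uniform(0, 8, size=(20, 12, 3))
        # keep D-H ~1 Å so angles are well defined
        for r in range(6):
            coords[:, 2 * r + 1] = coords[:, 2 * r] + rng.normal(
                0, 0.4, size=(20, 3)) + [1.0, 0, 0]
        traj = make_traj(atoms, coords, bonds=bonds)
        events = detect_hbonds(traj, min_consecutive=2)
        got = sorted((e.atoms[0], e.atoms[1], e.atoms[2],
                      e.window.start_frame, e.window.end_frame)
                     for e in events)
        triples = [(2 * r, 2 * r + 1, 2 * s)
                   for r in range(6) for s in range(6) if s != r]
        assert got == brute_hbonds(traj, triples, 2.4, 130.0, 2)

    @pytest.mark.parametrize("seed", range(3))
    def test_cation_pi_equivalence(self, seed):
        rng = np.random.default_rng(3000 + seed)
        spec = []
        for nm in ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"):
            spec.append((nm, "C", 1, "TRP", "PROT",
                         {"aromatic_ring_member"}))
        spec += [("N", "N", 10, "TOYL", "MEMB", {"choline_nitrogen"}),
                 ("N", "N", 11, "TOYL", "MEMB", {"choline_nitrogen"})]
        atoms = make_atoms(spec)
        ring0 = np.array([(1.39 * np.cos(a), 1.39 * np.sin(a), 0.0)
                          for a in np.radians(np.arange(0, 360, 60))])
        coords = np.empty((25, 8, 3))
        coords[:, :6] = ring0
        coords[:, 6:] = rng.uniform(-8, 8, size=(25, 2, 3))
        traj = make_traj(atoms, coords)
        events = detect_cation_pi(traj, min_consecutive=2)
        got = sorted((e.atoms[:-1], e.atoms[-1], e.window.start_frame,
                      e.window.end_frame) for e in events)
        assert got == brute_cation_pi(traj, [list(range(6))], [6, 7],
                                      7.0, 2)


class TestInventoryAndConsensus:
    def _inventory(self, distances):
        traj = two_carbon_traj(distances)
        events = detect_hydrophobic(traj)
        return build_inventory(events, traj.n_frames, traj.frame_interval)

    def test_occupancy_fraction(self):
        inv = self._inventory([2.8] * 10 + [8.0] * 10)
        assert inv.table["occupancy"].iloc[0] == pytest.approx(0.5)

    def test_consensus_keeps_shared_drops_unshared(self):
        inv_a = self._inventory([2.8] * 20)
        inv_b = self._inventory([2.8] * 10 + [8.0] * 10)
        inv_c = self._inventory([8.0] * 20)       # never in contact
        cons = replica_consensus([inv_a, inv_b])
        assert len(cons.table) == 1
        assert cons.table["occupancy"].iloc[0] == pytest.approx(0.75)
        assert cons.table["occupancy_rep0"].iloc[0] == pytest.approx(1.0)
        cons2 = replica_consensus([inv_a, inv_c])
        assert cons2.table.empty

    def test_single_replica_consensus_is_identity(self):
        inv = self._inventory([2.8] * 20)
        cons = replica_consensus([inv])
        assert cons.keys() == inv.keys()
        assert cons.table["occupancy"].iloc[0] == pytest.approx(1.0)


class TestWindowedSeries:
    def test_full_and_half_occupancy_windows(self):
        # contact present frames 0-9 of a 20-frame run, 1 ns spacing
        traj = two_carbon_traj([2.8] * 10 + [8.0] * 10)
        events = detect_hydrophobic(traj)
        sel = {events[0].residue_pair[0]}
        series = windowed_contact_series(events, 5.0, sel, traj.n_frames,
                                         traj.frame_interval)
        assert list(series["mean_contacts"]) == pytest.approx(
            [1.0, 1.0, 0.0, 0.0])
        series10 = windowed_contact_series(events, 20.0, sel,
                                           traj.n_frames,
                                           traj.frame_interval)
        assert list(series10["mean_contacts"]) == pytest.approx([0.5])

    def test_non_multiple_window_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            windowed_contact_series([], 2.5, {"x"}, 10, 2.0)

    def test_empty_selection_is_empty_series(self):
        assert windowed_contact_series([], 5.0, set(), 10, 1.0).empty

    def test_matches_per_frame_recount(self, rng):
        traj = random_system(rng, n_atoms=20, n_frames=40)
        events = detect_hydrophobic(traj, cutoff=4.0)
        sel = {a.residue_key for a in traj.topology}
        series = windowed_contact_series(events, 10.0, sel, traj.n_frames,
                                         traj.frame_interval)
        # independent recount from event windows
        counts = np.zeros(traj.n_frames)
        seen = {}
        for e in events:
            m = seen.setdefault(e.residue_pair,
                                np.zeros(traj.n_frames, bool))
            m[e.window.start_frame:e.window.end_frame + 1] = True
        for m in seen.values():
            counts += m
        for k, row in series.iterrows():
            lo = int(row["window_start_ns"])
            hi = min(lo + 10, traj.n_frames)
            assert row["mean_contacts"] == pytest.approx(
                counts[lo:hi].mean())
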