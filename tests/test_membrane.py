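"""Membrane-referenced descriptors: binding detection, insertion depth,
tilt, density profiles and minimum-distance series."""

import numpy as np
import pytest

from memgate.core import FrameWindow, TopologyError
from memgate.membrane import (density_profile, depth_of_insertion,
                              detect_binding_event, min_distance_series,
                              proximal_leaflet_reference, tilt_series)
from memgate.geometry import BilayerReference
from memgate.synth import ScenarioSpec, build_bilayer_slab, build_scenario

from conftest import make_atoms, make_traj, mi_dist


def approach_traj(distances):
    """A probe atom approaching a fixed target along z; per-frame gap
    given by ``distances`` (Å)."""
    atoms = make_atoms([
        ("C1", "C", 1, "ALA", "PROT", set()),
        ("P", "P", 2, "TOYL", "MEMB", {"phosphorus"}),
    ])
    coords = [np.array([[0.0, 0.0, d], [0.0, 0.0, 0.0]])
              for d in distances]
    return make_traj(atoms, coords)


class TestBindingEvent:
    def test_scripted_approach_found_at_crossing(self):
        d = [20.0] * 50 + [3.0] * 50
        traj = approach_traj(d)
        assert detect_binding_event(traj, [0], [1], cutoff=4.0,
                                    dwell=5.0) == 50

    def test_transient_touch_rejected(self):
        d = [20.0] * 10 + [3.0] + [20.0] * 10
        traj = approach_traj(d)
        assert detect_binding_event(traj, [0], [1], cutoff=4.0,
                                    dwell=5.0) is None

    def test_never_binding_returns_none(self):
        traj = approach_traj([20.0] * 10)
        assert detect_binding_event(traj, [0], [1], cutoff=4.0,
                                    dwell=2.0) is None

    def test_dwell_below_frame_interval_rejected(self):
        traj = approach_traj([3.0] * 5)
        with pytest.raises(ValueError, match="dwell"):
            detect_binding_event(traj, [0], [1], cutoff=4.0, dwell=0.5)

    def test_monotone_in_cutoff(self):
        d = list(np.linspace(20.0, 2.0, 40)) + [2.0] * 20
        traj = approach_traj(d)
        frames = [detect_binding_event(traj, [0], [1], cutoff=c,
                                       dwell=3.0)
                  for c in (3.0, 4.0, 6.0, 9.0)]
        assert all(f is not None for f in frames)
        assert frames == sorted(frames, reverse=True)

    def test_recovers_planted_binding(self, bound_scenario):
        replica_set, log = bound_scenario
        traj = replica_set.replicas[0]
        prot = [a.atom_id for a in traj.topology
                if a.segment_id == "PROT"]
        memb = [a.atom_id for a in traj.topology
                if a.segment_id == "MEMB"]
        got = detect_binding_event(traj, prot, memb, cutoff=4.0,
                                   dwell=10.0)
        assert got == log.by_kind("binding")[0].present_window.start_frame


class TestDepthOfInsertion:
    def _protein_on_plane(self, cb_z, resname="ALA", anchor="CB"):
        spec = [("CA", "C", 1, resname, "PROT", {"alpha_carbon"})]
        if anchor == "CB":
            spec.append(("CB", "C", 1, resname, "PROT", {"beta_carbon"}))
        spec.append(("P", "P", 100, "TOYL", "MEMB", {"phosphorus"}))
        atoms = make_atoms(spec)
        n = len(atoms)
        coords = [np.zeros((n, 3))]
        coords[0][-1] = [0.0, 0.0, 20.0]          # phosphorus plane
        coords[0][n - 2 if anchor == "CB" else 0, 2] = cb_z
        traj = make_traj(atoms, coords)
        ref = BilayerReference(plane_z=np.array([20.0]), averaged_z=20.0,
                               window=FrameWindow(0, 0),
                               leaflet_ids={"upper": [n - 1]})
        return traj, ref

    @pytest.mark.parametrize("cb_z,expected", [
        (20.0, 0.0), (18.0, -2.0), (21.0, 1.0)])
    def test_signed_depth_of_cb(self, cb_z, expected):
        traj, ref = self._protein_on_plane(cb_z)
        prof = depth_of_insertion(traj, ref, FrameWindow(0, 0),
                                  protein_ids=[0, 1])
        assert prof.table["depth_mean"].iloc[0] == pytest.approx(expected)

    def test_glycine_uses_alpha_carbon(self):
        traj, ref = self._protein_on_plane(21.0, resname="GLY",
                                           anchor="CA")
        prof = depth_of_insertion(traj, ref, FrameWindow(0, 0),
                                  protein_ids=[0])
        assert prof.table["anchor"].iloc[0] == "CA"
        assert prof.table["depth_mean"].iloc[0] == pytest.approx(1.0)

    def test_residue_without_anchors_is_error(self):
        atoms = make_atoms([("O", "O", 1, "ALA", "PROT", set())])
        traj = make_traj(atoms, [np.zeros((1, 3))])
        ref = BilayerReference(plane_z=np.array([0.0]), averaged_z=0.0,
                               window=FrameWindow(0, 0), leaflet_ids={})
        with pytest.raises(TopologyError, match="neither"):
            depth_of_insertion(traj, ref, FrameWindow(0, 0),
                               protein_ids=[0])

    def test_invariant_under_joint_z_translation(self, bound_scenario):
        replica_set, log = bound_scenario
        traj = replica_set.replicas[0]
        prot = [a.atom_id for a in traj.topology
                if a.segment_id == "PROT"]
        window = FrameWindow(log.by_kind("binding")[0]
                             .present_window.start_frame,
                             traj.n_frames - 1)
        ref = proximal_leaflet_reference(traj, prot, window)
        prof = depth_of_insertion(traj, ref, window, protein_ids=prot)

        shifted = make_traj(traj.topology,
                            [fr.coords + [0.0, 0.0, 13.0]
                             for fr in traj.frames],
                            box=traj.frames[0].box,
                            bonds=traj.bonds,
                            frame_interval=traj.frame_interval)
        ref2 = proximal_leaflet_reference(shifted, prot, window)
        prof2 = depth_of_insertion(shifted, ref2, window,
                                   protein_ids=prot)
        np.testing.assert_allclose(prof2.table["depth_mean"],
                                   prof.table["depth_mean"], atol=1e-9)


class TestTilt:
    def test_constant_scripted_angle(self):
        atoms = make_atoms([("CA", "C", 565, "ALA", "PROT", set()),
                            ("CA", "C", 591, "THR", "PROT", set())])
        v = np.array([np.sin(np.radians(40.0)), 0.0,
                      np.cos(np.radians(40.0))])
        coords = [np.array([[0.0, 0.0, 0.0], 10.0 * v])] * 6
        traj = make_traj(atoms, coords)
        series, mean, sd = tilt_series(traj, 0, 1)
        np.testing.assert_allclose(series, 40.0, atol=1e-9)
        assert mean == pytest.approx(40.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_axis_along_normal_is_zero(self):
        atoms = make_atoms([("A", "C", 1, "ALA", "PROT", set()),
                            ("B", "C", 2, "ALA", "PROT", set())])
        coords = [np.array([[0, 0, 0], [0, 0, 8.0]])]
        series, mean, _ = tilt_series(make_traj(atoms, coords), 0, 1)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_scripted_wobble_statistics(self, rng):
        atoms = make_atoms([("A", "C", 1, "ALA", "PROT", set()),
                            ("B", "C", 2, "ALA", "PROT", set())])
        angles = 40.0 + 5.0 * np.sin(np.linspace(0, 8 * np.pi, 200))
        coords = [np.array([[0.0, 0.0, 0.0],
                            [10 * np.sin(np.radians(a)), 0.0,
                             10 * np.cos(np.radians(a))]])
                  for a in angles]
        series, mean, sd = tilt_series(make_traj(atoms, coords), 0, 1)
        np.testing.assert_allclose(series, angles, atol=1e-9)
        assert mean == pytest.approx(angles.mean())
        assert sd == pytest.approx(angles.std())


class TestDensityProfile:
    def _uniform_traj(self, n=100, z=0.0):
        atoms = make_atoms([(f"C{i}", "C", i, "LIG", "SYS", set())
                            for i in range(n)])
        coords = [np.column_stack([np.arange(n) % 10,
                                   np.arange(n) // 10,
                                   np.full(n, z)])]
        return make_traj(atoms, coords)

    def test_point_mass_lands_in_one_bin(self):
        traj = self._uniform_traj(100, z=0.0)
        prof = density_profile(traj, {"g": list(range(100))},
                               FrameWindow(0, 0), bin_width=1.0,
                               weighting="number")
        counts = prof.counts["g"]
        assert counts.sum() == pytest.approx(100.0)
        assert counts.max() == pytest.approx(100.0)

    def test_integral_conserves_total_weight(self):
        traj = self._uniform_traj(64, z=3.3)
        prof = density_profile(traj, {"g": list(range(64))},
                               FrameWindow(0, 0), weighting="electron")
        assert prof.counts["g"].sum() == pytest.approx(64 * 6)  # carbon Z

    def test_bin_refinement_preserves_integral_exactly(self, rng):
        spec = ScenarioSpec(n_lipids_per_leaflet=16, n_frames=3,
                            noise_sigma=0.4, seed=5)
        traj = build_bilayer_slab(spec)
        ids = list(range(traj.n_atoms))
        prof1 = density_profile(traj, {"g": ids}, FrameWindow(0, 2),
                                bin_width=2.0, z_range=(-64.0, 64.0))
        prof2 = density_profile(traj, {"g": ids}, FrameWindow(0, 2),
                                bin_width=1.0, z_range=(-64.0, 64.0))
        assert prof1.counts["g"].sum() == prof2.counts["g"].sum()

    def test_noiseless_slab_profile_symmetric(self):
        traj = build_bilayer_slab(ScenarioSpec(n_lipids_per_leaflet=16,
                                               n_frames=1))
        ids = list(range(traj.n_atoms))
        # edges at x.25 / x.75 so no template coordinate (all at
        # multiples of 0.5 Å) sits exactly on a bin edge
        prof = density_profile(traj, {"g": ids}, FrameWindow(0, 0),
                               bin_width=0.5, z_range=(-40.25, 40.25))
        np.testing.assert_allclose(prof.density["g"],
                                   prof.density["g"][::-1], atol=1e-12)

    def test_empty_group_gives_empty_profile(self):
        traj = self._uniform_traj(4)
        prof = density_profile(traj, {"none": []}, FrameWindow(0, 0))
        assert prof.counts["none"].sum() == 0


class TestMinDistanceSeries:
    def test_planted_closest_pair(self):
        atoms = make_atoms([("A", "C", 1, "ALA", "PROT", set()),
                            ("B", "C", 2, "TOYL", "MEMB", set()),
                            ("C", "C", 3, "TOYL", "MEMB", set())])
        coords = [np.array([[0, 0, 0], [4.2, 0, 0], [9.0, 0, 0.0]])]
        series = min_distance_series(make_traj(atoms, coords), [0], [1, 2])
        assert series[0] == pytest.approx(4.2)

    def test_coincident_atoms_give_zero(self):
        atoms = make_atoms([("A", "C", 1, "ALA", "PROT", set()),
                            ("B", "C", 2, "TOYL", "MEMB", set())])
        coords = [np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])]
        series = min_distance_series(make_traj(atoms, coords), [0], [1])
        assert series[0] == 0.0

    def test_matches_brute_force(self, rng):
        from conftest import random_system
        traj = random_system(rng, n_atoms=40, n_frames=10)
        ga, gb = list(range(20)), list(range(20, 40))
        series = min_distance_series(traj, ga, gb)
        for k, fr in enumerate(traj.frames):
            expect = min(mi_dist(fr.coords[i], fr.coords[j], fr.box)
                         for i in ga for j in gb)
            assert series[k] == pytest.approx(expect)
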