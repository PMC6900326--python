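"""Geometric detectors vs brute-force oracles, torsions, occupancies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    brute_force_hbonds,
    brute_force_metal,
    brute_force_salt_bridges,
    events_as_set,
    make_model,
    random_polar_model,
    water_atom,
)
from hydronet.errors import AtomNotFoundError, DegenerateTorsionError
from hydronet.interactions import (
    InteractionEvent,
    TorsionSpec,
    detect_hbonds,
    detect_metal_coordination,
    detect_pi_T,
    detect_salt_bridges,
    dihedral,
    measure_distance,
    measure_torsion,
    occupancy,
    pair_key,
    residue_pair_key,
)
from hydronet.io import StructureModel


class TestDistance:
    def test_three_four_five(self):
        m = make_model(
            [("CA", "C", "ALA", 1, (0, 0, 0)), ("CB", "C", "ALA", 2, (3, 4, 0))]
        )
        assert measure_distance(m, (1, "CA"), (2, "CB")) == pytest.approx(5.0)

    def test_self_distance_zero(self):
        m = make_model([("CA", "C", "ALA", 1, (1, 2, 3))])
        assert measure_distance(m, (1, "CA"), (1, "CA")) == 0.0

    def test_missing_atom_names_key(self):
        m = make_model([("CA", "C", "ALA", 1, (0, 0, 0))])
        with pytest.raises(AtomNotFoundError, match="OD2"):
            measure_distance(m, (1, "CA"), (9, "OD2"))


def _four_points_with_dihedral(angle_deg):
    """p0-p1-p2-p3 constructed by rotating p3 about the p1-p2 bond."""
    t = np.radians(angle_deg)
    p0 = np.array([1.0, 1.0, 0.0])
    p1 = np.array([1.0, 0.0, 0.0])
    p2 = np.array([0.0, 0.0, 0.0])
    p3 = np.array([-1.0, np.cos(t), np.sin(t)])
    return p0, p1, p2, p3


class TestTorsion:
    @pytest.mark.parametrize("angle", [0.0, 70.0, -70.0, 120.0, 180.0, -135.0])
    def test_constructed_dihedral_recovered(self, angle):
        got = dihedral(*_four_points_with_dihedral(angle))
        expected = 180.0 if angle == -180.0 else angle
        assert got == pytest.approx(expected, abs=1e-6)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateTorsionError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_measure_torsion_on_model(self):
        pts = _four_points_with_dihedral(70.0)
        m = make_model(
            [
                ("C12", "C", "LIG", 1, tuple(pts[0])),
                ("C4", "C", "LIG", 1, tuple(pts[1])),
                ("C3", "C", "LIG", 1, tuple(pts[2])),
                ("C2", "C", "LIG", 1, tuple(pts[3])),
            ]
        )
        spec = TorsionSpec("chi1", [(1, "C12"), (1, "C4"), (1, "C3"), (1, "C2")])
        assert measure_torsion(m, spec) == pytest.approx(70.0, abs=1e-6)

    def test_duplicate_atoms_rejected(self):
        with pytest.raises(ValueError):
            TorsionSpec("bad", [(1, "C1"), (1, "C1"), (1, "C2"), (1, "C3")])


class TestHbonds:
    def test_carboxylate_to_amine_at_2p74(self):
        m = make_model(
            [
                ("OD2", "O", "ASP", 1025, (0, 0, 0)),
                ("N1", "N", "LIG", 2001, (2.74, 0, 0)),
            ]
        )
        events = detect_hbonds(m)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(2.74)

    def test_beyond_cutoff_is_silent(self):
        m = make_model(
            [
                ("OD2", "O", "ASP", 1025, (0, 0, 0)),
                ("N1", "N", "LIG", 2001, (3.6, 0, 0)),
            ]
        )
        assert detect_hbonds(m, d_max=3.5) == []

    def test_intra_residue_and_peptide_pairs_excluded(self):
        m = make_model(
            [
                ("N", "N", "GLY", 1, (0, 0, 0)),
                ("O", "O", "GLY", 1, (2.8, 0, 0)),  # same residue as N(1)
                ("N", "N", "GLY", 2, (2.8, 1.2, 0)),  # peptide neighbour of O(1)
                ("N", "N", "GLY", 5, (2.8, -1.2, 0)),  # distant residue: allowed
            ]
        )
        events = detect_hbonds(m)
        # only O(1)...N(5) survives: N(1)-O(1) intra-residue, O(1)-N(2) is a
        # peptide 1-3 pair, and N-N pairs have no acceptor
        assert [(e.atom_a[1], e.atom_b[1]) for e in events] == [(1, 5)]
        assert {events[0].atom_a[3], events[0].atom_b[3]} == {"O", "N"}


class TestSaltBridges:
    def test_glu_lys_pair(self):
        m = make_model(
            [
                ("OE1", "O", "GLU", 935, (0, 0, 0)),
                ("NZ", "N", "LYS", 938, (2.7, 0, 0)),
            ]
        )
        events = detect_salt_bridges(m)
        assert len(events) == 1 and events[0].kind == "salt_bridge"

    def test_beyond_default_cutoff(self):
        m = make_model(
            [
                ("OE1", "O", "GLU", 935, (0, 0, 0)),
                ("NZ", "N", "LYS", 938, (4.5, 0, 0)),
            ]
        )
        assert detect_salt_bridges(m) == []


class TestMetal:
    def test_cu_his_contact(self):
        m = make_model(
            [
                ("CU", "CU", "CU", 3052, (0, 0, 0)),
                ("NE2", "N", "HIS", 1026, (2.1, 0, 0)),
            ]
        )
        events = detect_metal_coordination(m, "element CU")
        assert len(events) == 1 and events[0].kind == "metal_coord"

    def test_water_beyond_cutoff(self):
        m = StructureModel(
            [
                make_model([("CU", "CU", "CU", 3047, (0, 0, 0))]).atoms[0],
                water_atom(2090, (3.4, 0, 0)),
            ]
        )
        assert detect_metal_coordination(m, "element CU") == []

    def test_empty_metal_selection_rejected(self):
        m = make_model([("CA", "C", "ALA", 1, (0, 0, 0))])
        with pytest.raises(ValueError):
            detect_metal_coordination(m, "element CU")


def _hexagon(center, radius=1.39, tilt_deg=0.0):
    t = np.radians(tilt_deg)
    R = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])
    pts = []
    for k in range(6):
        a = np.pi / 3 * k
        pts.append(R @ np.array([radius * np.cos(a), radius * np.sin(a), 0]) + center)
    return pts


class TestPiT:
    def _model(self, tilt, offset):
        ring_a = _hexagon(np.zeros(3))
        ring_b = _hexagon(np.array(offset), tilt_deg=tilt)
        spec = [
            (f"C{i+1}", "C", "PHE", 209, tuple(p)) for i, p in enumerate(ring_a)
        ] + [(f"C{i+1}", "C", "LIG", 2001, tuple(p)) for i, p in enumerate(ring_b)]
        m = make_model(spec)
        keys_a = [(209, f"C{i+1}") for i in range(6)]
        keys_b = [(2001, f"C{i+1}") for i in range(6)]
        return m, keys_a, keys_b

    def test_t_shaped_fires(self):
        m, ka, kb = self._model(tilt=90.0, offset=(0, 0, 5.0))
        ev = detect_pi_T(m, ka, kb)
        assert ev is not None
        assert ev.extra == pytest.approx(90.0, abs=1e-6)
        assert ev.distance == pytest.approx(5.0, abs=1e-6)

    def test_parallel_stack_is_not_t(self):
        m, ka, kb = self._model(tilt=0.0, offset=(0, 0, 4.0))
        assert detect_pi_T(m, ka, kb) is None

    @pytest.mark.parametrize("tilt,offset,expect", [
        (75.0, (0, 0, 6.0), True),
        (45.0, (0, 0, 5.0), False),   # angle outside the T window
        (90.0, (0, 0, 8.0), False),   # centroids too far
        (90.0, (0, 0, 3.0), False),   # centroids too close
    ])
    def test_window_logic_matches_analytic_geometry(self, tilt, offset, expect):
        m, ka, kb = self._model(tilt=tilt, offset=offset)
        assert (detect_pi_T(m, ka, kb) is not None) is expect


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_detectors_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = random_polar_model(rng, n_atoms=80)
        assert events_as_set(detect_hbonds(m)) == brute_force_hbonds(m)
        assert events_as_set(detect_salt_bridges(m)) == brute_force_salt_bridges(m)
        if any(a.element == "CU" for a in m.atoms):
            assert events_as_set(
                detect_metal_coordination(m, "element CU")
            ) == brute_force_metal(m)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_detectors_invariant_under_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        m = random_polar_model(rng, n_atoms=40)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        t = rng.uniform(0, np.pi)
        k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)
        moved = m.with_coords(m.coords @ R.T + rng.uniform(-20, 20, 3))
        for detector in (detect_hbonds, detect_salt_bridges):
            a = {(e.atom_a, e.atom_b, round(e.distance, 5)) for e in detector(m)}
            b = {(e.atom_a, e.atom_b, round(e.distance, 5)) for e in detector(moved)}
            assert a == b


class TestOccupancy:
    def _events(self, frames, key=("A", 1025, "ASP", "OD2")):
        other = ("A", 2001, "LIG", "N1")
        return [InteractionEvent("hbond", key, other, 2.7, f) for f in frames]

    def test_three_of_six_is_fifty_percent(self):
        recs = occupancy(self._events([0, 2, 4]), frame_range=range(6))
        assert len(recs) == 1
        assert recs[0].of_percent == pytest.approx(50.0)

    def test_all_frames_is_hundred(self):
        recs = occupancy(self._events(range(10)), frame_range=range(10))
        assert recs[0].of_percent == 100.0

    def test_bernoulli_occupancy_recovered(self):
        rng = np.random.default_rng(42)
        frames = [f for f in range(1000) if rng.random() < 0.85]
        recs = occupancy(self._events(frames), frame_range=range(1000))
        assert recs[0].of_percent == pytest.approx(85.0, abs=3.0)

    def test_residue_grouping_at_least_atom_level(self):
        a1 = ("A", 1025, "ASP", "OD1")
        a2 = ("A", 1025, "ASP", "OD2")
        other = ("A", 2001, "LIG", "N1")
        events = [InteractionEvent("hbond", a1, other, 2.7, f) for f in (0, 1)]
        events += [InteractionEvent("hbond", a2, other, 2.7, f) for f in (2, 3)]
        atom_level = occupancy(events, pair_key, frame_range=range(4))
        res_level = occupancy(events, residue_pair_key, frame_range=range(4))
        assert max(r.of_percent for r in atom_level) == 50.0
        assert res_level[0].of_percent == 100.0

    def test_occupancy_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        m = random_polar_model(rng, n_atoms=60)
        small = {(e.atom_a, e.atom_b) for e in detect_hbonds(m, d_max=3.0)}
        large = {(e.atom_a, e.atom_b) for e in detect_hbonds(m, d_max=3.8)}
        assert small <= large

    def test_empty_frame_range_rejected(self):
        with pytest.raises(ValueError):
            occupancy([], frame_range=[])
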