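"""Conserved-water-site clustering, classification and matching."""

import numpy as np
import pytest

from conftest import make_model, water_atom
from hydronet.interactions import OccupancyRecord
from hydronet.io import Ensemble, StructureModel
from hydronet.waters import (
    CONSERVED,
    SEMI_CONSERVED,
    TRANSIENT,
    ClusterParams,
    WaterSite,
    classify_sites,
    cluster_water_sites,
    match_waters_between_structures,
)


def _water_ensemble(site_plan, n_frames, seed=0, jitter=0.1):
    """Frames holding one water oxygen per planted site.

    site_plan: list of (centroid, occupancy_p, id_period) triples.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        atoms = []
        for s_idx, (centroid, p, period) in enumerate(site_plan):
            if rng.random() < p:
                res_seq = 2000 + 100 * s_idx + (f // period) % 4
                pos = np.asarray(centroid, float) + rng.normal(0, jitter, 3)
                atoms.append(water_atom(res_seq, pos, serial=90000 + s_idx))
        # an anchor atom so frames are never empty
        atoms.append(
            make_model([("CA", "C", "ALA", 1, (50.0, 50.0, 50.0))]).atoms[0]
        )
        frames.append(StructureModel(atoms, model_id=f + 1))
    return Ensemble(frames)


class TestClustering:
    def test_single_stable_site(self):
        ens = _water_ensemble([((0, 0, 0), 1.0, 1000)], n_frames=100)
        sites = cluster_water_sites(ens)
        assert len(sites) == 1
        assert sites[0].of_percent == 100.0
        assert sites[0].conservation_class == CONSERVED
        assert np.allclose(sites[0].centroid, 0, atol=0.1)

    def test_two_separated_sites(self):
        ens = _water_ensemble(
            [((0, 0, 0), 1.0, 1000), ((10, 0, 0), 1.0, 1000)], n_frames=50
        )
        sites = cluster_water_sites(ens)
        assert len(sites) == 2
        assert all(s.of_percent == 100.0 for s in sites)

    def test_bernoulli_site_with_identity_exchange(self):
        """A site occupied ~85% of frames by a rotating cast of waters is one
        site, at the planted occupancy, with several distinct ids."""
        ens = _water_ensemble([((3, 1, 2), 0.85, 10)], n_frames=1000, seed=42)
        sites = cluster_water_sites(ens)
        assert len(sites) == 1
        assert sites[0].of_percent == pytest.approx(85.0, abs=3.0)
        assert len(sites[0].distinct_water_ids) >= 2

    def test_three_planted_occupancies_recovered(self):
        plan = [((0, 0, 0), 1.0, 10), ((6, 0, 0), 0.85, 10), ((0, 6, 0), 0.5, 10)]
        ens = _water_ensemble(plan, n_frames=1000, seed=7)
        sites = cluster_water_sites(ens)
        assert len(sites) == 3
        got = [s.of_percent for s in sites]
        assert got[0] == pytest.approx(100.0, abs=3.0)
        assert got[1] == pytest.approx(85.0, abs=3.0)
        assert got[2] == pytest.approx(50.0, abs=3.0)
        assert [s.site_id for s in sites] == ["WS1", "WS2", "WS3"]

    def test_zero_waters_gives_empty_list(self):
        ens = _water_ensemble([], n_frames=5)
        assert cluster_water_sites(ens) == []

    def test_deterministic(self):
        plan = [((0, 0, 0), 0.7, 5), ((4, 3, 0), 0.9, 5)]
        a = cluster_water_sites(_water_ensemble(plan, 200, seed=3))
        b = cluster_water_sites(_water_ensemble(plan, 200, seed=3))
        assert [s.site_id for s in a] == [s.site_id for s in b]
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.centroid, sb.centroid)
            assert [(m.frame, m.water_id) for m in sa.members] == [
                (m.frame, m.water_id) for m in sb.members
            ]

    def test_at_most_one_member_per_frame_per_site(self):
        # two waters jittering around nearby centroids
        plan = [((0, 0, 0), 1.0, 5), ((2.5, 0, 0), 1.0, 5)]
        ens = _water_ensemble(plan, 200, seed=5, jitter=0.3)
        for site in cluster_water_sites(ens):
            frames = [m.frame for m in site.members]
            assert len(frames) == len(set(frames))

    def test_assigned_waters_never_exceed_frame_waters(self):
        plan = [((0, 0, 0), 0.8, 5), ((2.2, 0, 0), 0.9, 5)]
        ens = _water_ensemble(plan, 100, seed=11, jitter=0.4)
        sites = cluster_water_sites(ens, ClusterParams(min_occupancy_report=0.0))
        per_frame = {}
        for s in sites:
            for m in s.members:
                per_frame[m.frame] = per_frame.get(m.frame, 0) + 1
        for f, count in per_frame.items():
            assert count <= len(ens.frames[f].water_oxygens())

    def test_smaller_cutoff_never_fewer_sites(self):
        plan = [((0, 0, 0), 1.0, 5), ((2.6, 0, 0), 1.0, 5)]
        ens = _water_ensemble(plan, 100, seed=9, jitter=0.5)
        loose = cluster_water_sites(ens, ClusterParams(link_cutoff=2.5, min_occupancy_report=0))
        tight = cluster_water_sites(ens, ClusterParams(link_cutoff=1.0, min_occupancy_report=0))
        assert len(tight) >= len(loose)

    def test_region_restriction(self):
        plan = [((0, 0, 0), 1.0, 5), ((30, 0, 0), 1.0, 5)]
        ens = _water_ensemble(plan, 50, seed=2)
        # anchor CA sits at (50,50,50); give it a companion near site 1
        for f in ens.frames:
            f.atoms.append(
                make_model([("N1", "N", "LIG", 2001, (1.0, 0.0, 0.0))]).atoms[0]
            )
            f._index = None
        sites = cluster_water_sites(ens, region="resname LIG", region_radius=6.0)
        assert len(sites) == 1
        assert np.allclose(sites[0].centroid, (0, 0, 0), atol=0.2)


class TestClassification:
    def _site(self, of):
        return WaterSite(
            site_id="WSx",
            centroid=np.zeros(3),
            occupancy=OccupancyRecord("WSx", int(of * 10), 1000),
        )

    @pytest.mark.parametrize(
        "of,expected",
        [(100.0, CONSERVED), (90.0, CONSERVED), (85.0, SEMI_CONSERVED),
         (60.0, SEMI_CONSERVED), (59.9, TRANSIENT), (0.1, TRANSIENT)],
    )
    def test_thresholds(self, of, expected):
        site = classify_sites([self._site(of)])[0]
        assert site.conservation_class == expected


class TestCrystalMatching:
    def _model(self, positions, start=2000):
        return StructureModel(
            [water_atom(start + i, p, serial=i + 1) for i, p in enumerate(positions)]
        )

    def test_identity_matches_all_at_zero(self):
        m = self._model([(0, 0, 0), (5, 0, 0), (0, 7, 0)])
        matches = match_waters_between_structures(m, m)
        assert len(matches) == 3
        assert all(d == 0.0 for _, _, d in matches)

    def test_displacement_beyond_cutoff_unmatched(self):
        ref = self._model([(0, 0, 0)])
        other = self._model([(2.0, 0, 0)])
        assert match_waters_between_structures(ref, other, cutoff=1.8) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_equal_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref_pos = rng.uniform(0, 8, (8, 3))
        oth_pos = ref_pos + rng.normal(0, 1.0, (8, 3))
        ref = self._model(ref_pos)
        other = self._model(oth_pos, start=3000)
        got = match_waters_between_structures(ref, other, cutoff=1.8)

        # exhaustive greedy min-distance oracle
        pairs = sorted(
            (float(np.linalg.norm(a - b)), i, j)
            for i, a in enumerate(ref_pos)
            for j, b in enumerate(oth_pos)
        )
        used_i, used_j, expected = set(), set(), []
        for d, i, j in pairs:
            if d > 1.8 or i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            expected.append((("W", 2000 + i), ("W", 3000 + j), round(d, 6)))
        assert [(a, b, round(d, 6)) for a, b, d in got] == sorted(
            expected, key=lambda t: t[2]
        )
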