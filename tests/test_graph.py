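"""Interaction graph assembly and recognition-path search."""

import networkx as nx
import numpy as np
import pytest

from conftest import make_model
from hydronet.errors import GraphConsistencyError
from hydronet.graph import (
    COVALENT,
    HBOND,
    METAL,
    build_graph,
    find_path,
    format_path,
)
from hydronet.interactions import InteractionEvent
from hydronet.io import Ensemble


def _chain_ensemble():
    """Three consecutive alanines, one frame."""
    model = make_model(
        [
            ("CA", "C", "ALA", 10, (0, 0, 0)),
            ("CA", "C", "ALA", 11, (4, 0, 0)),
            ("CA", "C", "ALA", 12, (8, 0, 0)),
        ]
    )
    return Ensemble([model])


class TestBuildGraph:
    def test_bare_chain_gets_covalent_edges_only(self):
        g = build_graph(_chain_ensemble(), events=[], sites=[])
        assert sorted(g.nodes) == ["ALA10", "ALA11", "ALA12"]
        assert g.number_of_edges() == 2
        assert all(d["kind"] == COVALENT for _, _, d in g.edges(data=True))

    def test_recognition_component_wires_up(self):
        model = make_model(
            [
                ("N1", "N", "SRO", 2001, (0, 0, 0)),
                ("OD2", "O", "ASP", 1025, (2.7, 0, 0)),
                ("NE2", "N", "HIS", 1026, (8, 0, 0)),
                ("CU", "CU", "CU", 3052, (10.1, 0, 0)),
            ]
        )
        ens = Ensemble([model])
        events = [
            InteractionEvent(
                "hbond", ("A", 2001, "SRO", "N1"), ("A", 1025, "ASP", "OD2"), 2.7, 0
            ),
            InteractionEvent(
                "metal_coord", ("A", 1026, "HIS", "NE2"), ("A", 3052, "CU", "CU"), 2.1, 0
            ),
        ]
        g = build_graph(ens, events, sites=[])
        assert g.has_edge("SRO:N1", "ASP1025")
        assert g.edges["SRO:N1", "ASP1025"]["kind"] == HBOND
        assert g.has_edge("ASP1025", "HIS1026")  # covalent adjacency
        assert g.edges["HIS1026", "CU3052"]["kind"] == METAL
        comp = nx.node_connected_component(g, "SRO:N1")
        assert comp == {"SRO:N1", "ASP1025", "HIS1026", "CU3052"}

    def test_occ_min_drops_subthreshold_edges(self):
        ens = Ensemble([_chain_ensemble().frames[0]] * 10)
        key_a = ("A", 10, "ALA", "CA")
        key_c = ("A", 12, "ALA", "CA")
        events = [InteractionEvent("hbond", key_a, key_c, 3.0, f) for f in range(5)]
        low = build_graph(ens, events, sites=[], occ_min=50.0)
        high = build_graph(ens, events, sites=[], occ_min=90.0)
        assert low.has_edge("ALA10", "ALA12")
        assert not high.has_edge("ALA10", "ALA12")
        assert low.number_of_edges() - high.number_of_edges() == 1

    def test_unknown_event_atom_raises(self):
        events = [
            InteractionEvent(
                "hbond", ("A", 10, "ALA", "CA"), ("A", 99, "TRP", "NE1"), 3.0, 0
            )
        ]
        with pytest.raises(GraphConsistencyError):
            build_graph(_chain_ensemble(), events, sites=[])


def _toy_graph():
    g = nx.Graph()
    for n, kind in [
        ("L:N1", "ligand_atom"), ("ASP1", "residue"), ("HIS2", "residue"),
        ("CU9", "metal"), ("WS1", "water_site"), ("GLU5", "residue"),
    ]:
        g.add_node(n, kind=kind, label=n)
    g.add_edge("L:N1", "ASP1", kind=HBOND, of_percent=100.0)
    g.add_edge("ASP1", "HIS2", kind=COVALENT, of_percent=100.0)
    g.add_edge("HIS2", "CU9", kind=METAL, of_percent=100.0)
    g.add_edge("L:N1", "WS1", kind=HBOND, of_percent=60.0)
    g.add_edge("WS1", "CU9", kind=METAL, of_percent=55.0)
    return g


class TestFindPath:
    def test_zero_hop(self):
        p = find_path(_toy_graph(), "L:N1", ["L:N1"])
        assert p.hops == 0 and p.nodes == ["L:N1"]

    def test_disconnected_returns_none(self):
        p = find_path(_toy_graph(), "GLU5", ["CU9"])
        assert p is None

    def test_missing_source_raises(self):
        with pytest.raises(ValueError):
            find_path(_toy_graph(), "NOPE", ["CU9"])

    def test_equal_hops_prefers_higher_min_occupancy(self):
        # two 2-hop routes L:N1->CU9: via WS1 (min 55) and... make one
        g = _toy_graph()
        g.add_edge("L:N1", "HIS2", kind=HBOND, of_percent=90.0)
        p = find_path(g, "L:N1", ["CU9"])
        assert p.hops == 2
        assert p.nodes == ["L:N1", "HIS2", "CU9"]
        assert p.min_occupancy == 90.0

    def test_max_hops_constraint(self):
        g = _toy_graph()
        g.remove_edge("L:N1", "WS1")
        assert find_path(g, "L:N1", ["CU9"], max_hops=2) is None
        assert find_path(g, "L:N1", ["CU9"], max_hops=3) is not None

    def test_forbidden_kinds(self):
        p = find_path(_toy_graph(), "L:N1", ["CU9"], forbidden_kinds=[METAL])
        assert p is None

    def test_water_site_count(self):
        g = _toy_graph()
        g.remove_edge("L:N1", "ASP1")
        p = find_path(g, "L:N1", ["CU9"])
        assert p.nodes == ["L:N1", "WS1", "CU9"]
        assert p.water_site_count == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_hop_count_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        g = nx.gnp_random_graph(n, 0.15, seed=seed)
        h = nx.Graph()
        for u, v in g.edges:
            h.add_edge(f"N{u}", f"N{v}", kind=HBOND, of_percent=float(rng.uniform(50, 100)))
        for u in g.nodes:
            if f"N{u}" not in h:
                h.add_node(f"N{u}")
        src, tgt = f"N{0}", f"N{n-1}"
        got = find_path(h, src, [tgt])
        try:
            expected = nx.shortest_path_length(h, src, tgt)
        except nx.NetworkXNoPath:
            expected = None
        if expected is None:
            assert got is None
        else:
            assert got.hops == expected

    def test_adding_edge_never_increases_hops(self):
        g = _toy_graph()
        before = find_path(g, "L:N1", ["CU9"]).hops
        g.add_edge("L:N1", "CU9", kind=HBOND, of_percent=70.0)
        after = find_path(g, "L:N1", ["CU9"]).hops
        assert after <= before


class TestFormatPath:
    def test_separators_reflect_edge_kinds(self):
        g = _toy_graph()
        g.remove_edge("L:N1", "WS1")
        p = find_path(g, "L:N1", ["CU9"])
        assert format_path(p, g) == "L:N1…ASP1-HIS2-CU9"

    def test_water_bridge_renders_with_ellipses(self):
        g = _toy_graph()
        g.remove_edge("L:N1", "ASP1")
        p = find_path(g, "L:N1", ["CU9"])
        assert format_path(p, g) == "L:N1…WS1…CU9"

    def test_zero_hop_is_single_label(self):
        p = find_path(_toy_graph(), "CU9", ["CU9"])
        assert format_path(p, _toy_graph()) == "CU9"


class TestBenchmarkPaths:
    def test_planted_direct_path_formats_like_the_field(self, analysed_benchmark):
        ab = analysed_benchmark
        g = build_graph(
            ab["aligned"], ab["events"], ab["sites"], charged_atoms=["N1"]
        )
        p = find_path(g, "SRO:N1", ["CU3048"])
        assert p.nodes == ab["truth"].path_nodes
        assert (
            format_path(p, g)
            == "N1(+)…Asp1025-His1026-Cu3052-Cys1021-His1022-Cu3048"
        )

    def test_planted_water_bridge_path(self, analysed_benchmark):
        ab = analysed_benchmark
        g = build_graph(
            ab["aligned"], ab["events"], ab["sites"], charged_atoms=["N1"]
        )
        p = find_path(g, "SRO:N1", ["CU3047"])
        assert p.hops == 7
        assert p.water_site_count == 1
        text = format_path(p, g)
        assert "…WS" in text and text.endswith("Cu3047")
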