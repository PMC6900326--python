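"""Typed interaction graph and ligand-to-metal recognition-path search.

Nodes are ligand atoms, protein residues (side-chain atoms collapsed), water
sites and metal ions.  Edges are hydrogen bonds (weighted by occupation
frequency and admitted only above an occupancy floor), covalent backbone
adjacency between sequence-consecutive residues, and metal coordination.
A recognition path is the minimal-hop route from a ligand atom to a metal
centre; among equal-hop routes the one whose weakest hydrogen bond has the
highest occupancy wins, and remaining ties break lexicographically so the
search is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import GraphConsistencyError
from .interactions import InteractionEvent
from .io import DEFAULT_WATER_RESNAMES, Ensemble, STANDARD_AA
from .waters import WaterSite

HBOND = "hbond"
COVALENT = "covalent_adjacent"
METAL = "metal_coord"

_COVALENT_KINDS = {COVALENT, METAL}


@dataclass
class PathResult:
    """A recognition path: nodes, edge kinds, and path-level summaries."""

    nodes: list[str]
    edge_kinds: list[str]
    min_occupancy: float

    @property
    def hops(self) -> int:
        return len(self.edge_kinds)

    @property
    def water_site_count(self) -> int:
        return sum(1 for n in self.nodes if n.startswith("WS"))


def _residue_node(chain: str, res_seq: int, res_name: str) -> str:
    return f"{res_name}{res_seq}"


def _pretty_residue(node: str) -> str:
    i = 0
    while i < len(node) and not node[i].isdigit() and node[i] != "-":
        i += 1
    return node[:i].capitalize() + node[i:]


def build_graph(
    ensemble: Ensemble,
    events: Iterable[InteractionEvent],
    sites: Sequence[WaterSite] = (),
    occ_min: float = 50.0,
    ligand_resnames: Iterable[str] | None = None,
    charged_atoms: Iterable[str] = (),
    water_resnames=DEFAULT_WATER_RESNAMES,
) -> nx.Graph:
    """Assemble the typed interaction graph from per-frame events and sites.

    Non-covalent edges (hydrogen bond, salt bridge, metal coordination)
    require site-wise occupation frequency >= ``occ_min`` %, so a contact
    seen in a stray frame never wires a spurious route.  Individual waters
    are replaced by their
    water-site node; events whose water belongs to no reported site are
    dropped.  Residues with consecutive ``res_seq`` on one chain receive
    covalent_adjacent edges.
    """
    ref = ensemble.frames[0]
    n_frames = ensemble.n_frames
    ligand_resnames = set(ligand_resnames or ())
    charged_atoms = set(charged_atoms)

    # classify the shared atom table
    node_of_atom: dict[tuple, str] = {}
    g = nx.Graph()
    residues_by_chain: dict[str, list[tuple[int, str]]] = {}
    known_nonwater = set()
    for a in ref.atoms:
        if a.is_water(water_resnames):
            continue
        known_nonwater.add((a.chain, a.res_seq, a.name))
        if a.res_name in STANDARD_AA:
            node = _residue_node(a.chain, a.res_seq, a.res_name)
            if node not in g:
                g.add_node(node, kind="residue", label=_pretty_residue(node))
                residues_by_chain.setdefault(a.chain, []).append((a.res_seq, node))
        elif a.is_metal():
            node = f"{a.element}{a.res_seq}"
            g.add_node(node, kind="metal", label=a.element.capitalize() + str(a.res_seq))
        elif not ligand_resnames or a.res_name in ligand_resnames:
            # heteroresidue treated as ligand: polar atoms become nodes
            if a.element in ("N", "O", "S"):
                node = f"{a.res_name}:{a.name}"
                label = a.name + ("(+)" if node in charged_atoms or a.name in charged_atoms else "")
                g.add_node(node, kind="ligand_atom", label=label)
            else:
                continue
        else:
            continue
        node_of_atom[(a.chain, a.res_seq, a.name)] = node

    for chain, residues in residues_by_chain.items():
        residues = sorted(set(residues))
        for (s1, n1), (s2, n2) in zip(residues, residues[1:]):
            if s2 == s1 + 1:
                g.add_edge(n1, n2, kind=COVALENT, distance=None, of_percent=100.0)

    # water -> site lookup
    site_of_water: dict[tuple[int, tuple], str] = {}
    for s in sites:
        for m in s.members:
            site_of_water[(m.frame, m.water_id)] = s.site_id
        g.add_node(s.site_id, kind="water_site", label=s.site_id)

    def endpoint(key, frame):
        chain, res_seq, res_name, name = key
        if res_name in water_resnames:
            return site_of_water.get((frame, (chain, res_seq)))
        node = node_of_atom.get((chain, res_seq, name))
        if node is None:
            if (chain, res_seq, name) not in known_nonwater:
                raise GraphConsistencyError(
                    f"event references atom {key} absent from the ensemble"
                )
        return node

    acc: dict[tuple, dict] = {}
    for e in events:
        na = endpoint(e.atom_a, e.frame)
        nb = endpoint(e.atom_b, e.frame)
        if na is None or nb is None or na == nb:
            continue
        kind = METAL if e.kind == "metal_coord" else HBOND
        edge = (kind,) + tuple(sorted((na, nb)))
        rec = acc.setdefault(edge, {"frames": set(), "distances": []})
        rec["frames"].add(e.frame)
        rec["distances"].append(e.distance)

    for (kind, na, nb), rec in sorted(acc.items()):
        of = 100.0 * len(rec["frames"]) / n_frames
        if of < occ_min:
            continue
        if g.has_edge(na, nb) and g.edges[na, nb]["kind"] == COVALENT:
            continue  # backbone adjacency outranks a detected contact
        g.add_edge(
            na,
            nb,
            kind=kind,
            distance=float(np.mean(rec["distances"])),
            of_percent=of,
        )
    return g


def find_path(
    graph: nx.Graph,
    source: str,
    targets: Iterable[str] | str,
    max_hops: int | None = None,
    required_kinds: Iterable[str] | None = None,
    forbidden_kinds: Iterable[str] | None = None,
) -> PathResult | None:
    """Minimal-hop path from ``source`` to any of ``targets``.

    Tie-breaks, in order: maximal minimum edge occupancy along the path,
    then lexicographically smallest node sequence.  Returns ``None`` when no
    path satisfies the constraints (distinct from raising on bad arguments).
    """
    if isinstance(targets, str):
        targets = [targets]
    targets = list(targets)
    if not targets:
        raise ValueError("targets must be non-empty")
    if source not in graph:
        raise ValueError(f"source node {source!r} not in graph")
    for t in targets:
        if t not in graph:
            raise ValueError(f"target node {t!r} not in graph")

    h = graph
    if forbidden_kinds:
        forbidden = set(forbidden_kinds)
        h = graph.edge_subgraph(
            [
                (u, v)
                for u, v, k in graph.edges(data="kind")
                if k not in forbidden
            ]
        ).copy()
        for n in [source, *targets]:
            if n not in h:
                h.add_node(n)
    required = set(required_kinds) if required_kinds else None

    if source in targets:
        return PathResult(nodes=[source], edge_kinds=[], min_occupancy=100.0)

    lengths = nx.single_source_shortest_path_length(h, source)
    reachable = [(lengths[t], t) for t in targets if t in lengths]
    if not reachable:
        return None
    best_len = min(l for l, _ in reachable)
    if max_hops is not None and best_len > max_hops:
        return None

    candidates = []
    for length, t in reachable:
        if length != best_len:
            continue
        for nodes in nx.all_shortest_paths(h, source, t):
            kinds = [h.edges[u, v]["kind"] for u, v in zip(nodes, nodes[1:])]
            if required and not required.issubset(kinds):
                continue
            occs = [
                h.edges[u, v].get("of_percent", 100.0)
                for u, v in zip(nodes, nodes[1:])
            ]
            min_occ = min(occs) if occs else 100.0
            candidates.append((-min_occ, nodes, kinds))
    if not candidates:
        return None
    neg_occ, nodes, kinds = min(candidates, key=lambda c: (c[0], c[1]))
    return PathResult(nodes=nodes, edge_kinds=kinds, min_occupancy=-neg_occ)


def format_path(path: PathResult, graph: nx.Graph | None = None) -> str:
    """Human-readable path string: "..." for hydrogen bonds, "-" for
    covalent/coordination steps (e.g. N1(+)...Asp1025-His1026-Cu3052)."""

    def label(node):
        if graph is not None and node in graph:
            return graph.nodes[node].get("label", node)
        return node

    def is_site(node):
        if graph is not None and node in graph:
            return graph.nodes[node].get("kind") == "water_site"
        return node.startswith("WS")

    out = [label(path.nodes[0])]
    for i, (kind, node) in enumerate(zip(path.edge_kinds, path.nodes[1:])):
        through_water = is_site(node) or is_site(path.nodes[i])
        out.append("-" if kind in _COVALENT_KINDS and not through_water else "…")
        out.append(label(node))
    return "".join(out)


def graph_to_edge_table(graph: nx.Graph):
    """Edge list as a DataFrame (node_a, node_b, kind, distance_A, of_percent)."""
    import pandas as pd

    rows = [
        {
            "node_a": min(u, v),
            "node_b": max(u, v),
            "kind": d.get("kind"),
            "distance_A": d.get("distance"),
            "of_percent": d.get("of_percent"),
        }
        for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows).sort_values(["kind", "node_a", "node_b"]).reset_index(drop=True)
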