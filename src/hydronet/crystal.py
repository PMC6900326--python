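"""Geometry checks on single crystal structures.

These helpers measure the landmark geometry of a multicopper-oxidase
binding region directly from a deposited structure: the acidic-triad
carboxylate distances, the separations between mononuclear T1 copper
centres, the distance of a labile surface copper from its nearest T1
centre, and the chain of water molecules hydrogen-bonding a carboxylate to
a copper of the trinuclear cluster.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np

from .errors import AtomNotFoundError
from .interactions import measure_distance
from .io import DEFAULT_WATER_RESNAMES, Selection, StructureModel, select

#: default triad atoms: Asp1025 OD1, Glu935 OE1, Glu272 OE1
DEFAULT_TRIAD = ((1025, "OD1"), (935, "OE1"), (272, "OE1"))


def acidic_triad_distances(
    model: StructureModel, triad=DEFAULT_TRIAD
) -> dict[str, float]:
    """Pairwise distances (A) among the three triad carboxylate oxygens.

    Keys name the residue pairs, e.g. ``"1025-935"``.
    """
    out = {}
    for ka, kb in combinations(triad, 2):
        out[f"{ka[0]}-{kb[0]}"] = measure_distance(model, ka, kb)
    return out


def metal_separations(
    model: StructureModel, metal_selection: Selection | str = "element CU"
) -> dict[str, float]:
    """Pairwise metal-metal distances (A) for the selected metal atoms."""
    metals = select(model, metal_selection)
    out = {}
    for a, b in combinations(metals, 2):
        out[f"{a.name}{a.res_seq}-{b.name}{b.res_seq}"] = float(
            np.linalg.norm(a.coords - b.coords)
        )
    return out


def nearest_metal_distance(
    model: StructureModel,
    atom_key,
    metal_selection: Selection | str = "element CU",
    exclude_self: bool = True,
) -> tuple[str, float]:
    """Distance (A) from one atom to the nearest selected metal."""
    a = model.find_atom(atom_key)
    if a is None:
        raise AtomNotFoundError(f"atom {atom_key} not found")
    best = None
    for m in select(model, metal_selection):
        if exclude_self and m.key == a.key:
            continue
        d = float(np.linalg.norm(m.coords - a.coords))
        if best is None or d < best[1]:
            best = (f"{m.name}{m.res_seq}", d)
    if best is None:
        raise AtomNotFoundError("metal selection matches no other atoms")
    return best


def water_bridge(
    model: StructureModel,
    start_key,
    metal_key,
    hbond_max: float = 3.5,
    metal_max: float = 3.0,
    max_waters: int = 5,
    water_resnames=DEFAULT_WATER_RESNAMES,
) -> list[tuple] | None:
    """Shortest chain of waters hydrogen-bonding ``start_key`` to ``metal_key``.

    Water oxygens within ``hbond_max`` of each other (or of the start atom)
    and within ``metal_max`` of the metal form the search graph; returns the
    water ids (chain, res_seq) of the shortest bridge, ``None`` if there is
    none within ``max_waters`` waters.
    """
    start = model.find_atom(start_key)
    metal = model.find_atom(metal_key)
    if start is None or metal is None:
        raise AtomNotFoundError(f"missing atom: {start_key if start is None else metal_key}")
    waters = model.water_oxygens(water_resnames)
    g = nx.Graph()
    g.add_node("start")
    g.add_node("metal")
    for i, w in enumerate(waters):
        if np.linalg.norm(w.coords - start.coords) <= hbond_max:
            g.add_edge("start", i)
        if np.linalg.norm(w.coords - metal.coords) <= metal_max:
            g.add_edge(i, "metal")
    for i, wa in enumerate(waters):
        for j in range(i + 1, len(waters)):
            if np.linalg.norm(wa.coords - waters[j].coords) <= hbond_max:
                g.add_edge(i, j)
    try:
        nodes = nx.shortest_path(g, "start", "metal")
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None
    bridge = [(waters[n].chain, waters[n].res_seq) for n in nodes[1:-1]]
    return bridge if 0 < len(bridge) <= max_waters else None
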