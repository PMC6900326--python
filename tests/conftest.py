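"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every quantity by exhaustive scans or
direct formulas, independent of the library's KD-tree / graph machinery, so
detector tests compare two genuinely different routes to the same answer.
"""

from __future__ import annotations

import numpy as np
import pytest

from hydronet.interactions import (
    ACIDIC_ATOMS,
    BASIC_ATOMS,
    DonorAcceptorTable,
    detect_all_frames,
    detect_hbonds,
    detect_metal_coordination,
    detect_salt_bridges,
)
from hydronet.io import AtomRecord, StructureModel
from hydronet.superpose import align_ensemble
from hydronet.synthetic import make_benchmark, simulate_trajectory
from hydronet.waters import cluster_water_sites


def make_model(spec, model_id=1):
    """Build a StructureModel from (name, element, res_name, res_seq, xyz)
    tuples; chain A, serials sequential."""
    atoms = [
        AtomRecord(i + 1, name, element, res_name, res_seq, "A", np.array(xyz, float))
        for i, (name, element, res_name, res_seq, xyz) in enumerate(spec)
    ]
    return StructureModel(atoms, model_id=model_id)


def water_atom(res_seq, xyz, chain="W", serial=90000):
    return AtomRecord(serial, "O", "O", "HOH", res_seq, chain, np.array(xyz, float))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def _same_res(a, b):
    return (a.chain, a.res_seq, a.res_name) == (b.chain, b.res_seq, b.res_name)


def _peptide(a, b):
    if a.chain != b.chain or abs(a.res_seq - b.res_seq) != 1:
        return False
    lo, hi = (a, b) if a.res_seq < b.res_seq else (b, a)
    return lo.name in ("C", "O", "CA") and hi.name in ("N", "CA")


def brute_force_hbonds(model, d_max=3.5, table=None):
    """Exhaustive O(N^2) donor-acceptor scan; returns a set of
    (atom_a, atom_b, rounded distance)."""
    table = table or DonorAcceptorTable()
    out = set()
    atoms = model.atoms
    for i, a in enumerate(atoms):
        for b in atoms[i + 1 :]:
            ra, rb = table.role_of(a), table.role_of(b)
            ok = (ra in ("donor", "both") and rb in ("acceptor", "both")) or (
                rb in ("donor", "both") and ra in ("acceptor", "both")
            )
            if not ok or _same_res(a, b) or _peptide(a, b):
                continue
            d = float(np.linalg.norm(a.coords - b.coords))
            if d <= d_max:
                ka, kb = sorted((a.key, b.key))
                out.add((ka, kb, round(d, 6)))
    return out


def brute_force_salt_bridges(model, d_max=4.0):
    out = set()
    for a in model.atoms:
        if (a.res_name, a.name) not in ACIDIC_ATOMS:
            continue
        for b in model.atoms:
            if (b.res_name, b.name) not in BASIC_ATOMS:
                continue
            d = float(np.linalg.norm(a.coords - b.coords))
            if d <= d_max:
                ka, kb = sorted((a.key, b.key))
                out.add((ka, kb, round(d, 6)))
    return out


def brute_force_metal(model, d_max=3.0):
    metals = [a for a in model.atoms if a.element == "CU"]
    out = set()
    for m in metals:
        for b in model.atoms:
            if b.element not in ("N", "O", "S") or b.key == m.key:
                continue
            d = float(np.linalg.norm(m.coords - b.coords))
            if d <= d_max:
                ka, kb = sorted((m.key, b.key))
                out.add((ka, kb, round(d, 6)))
    return out


def events_as_set(events):
    return {(e.atom_a, e.atom_b, round(e.distance, 6)) for e in events}


_ATOM_POOL = [
    ("OD1", "O", "ASP"),
    ("OD2", "O", "ASP"),
    ("NZ", "N", "LYS"),
    ("NE2", "N", "HIS"),
    ("ND1", "N", "HIS"),
    ("OG", "O", "SER"),
    ("N", "N", "GLY"),
    ("O", "O", "GLY"),
    ("CA", "C", "GLY"),
    ("O", "O", "HOH"),
    ("N1", "N", "LIG"),
    ("O3", "O", "LIG"),
    ("CU", "CU", "CU"),
    ("CB", "C", "ALA"),
]


def random_polar_model(rng, n_atoms=100, box=14.0):
    """A random soup of donors/acceptors/waters/metals for oracle tests."""
    spec = []
    for i in range(n_atoms):
        name, element, res = _ATOM_POOL[rng.integers(len(_ATOM_POOL))]
        spec.append((name, element, res, int(i + 1), rng.uniform(0, box, 3)))
    return make_model(spec)


# ---------------------------------------------------------------------------
# session fixtures: one benchmark trajectory analysed once
# ---------------------------------------------------------------------------

BENCHMARK_SEED = 7
BENCHMARK_FRAMES = 200


@pytest.fixture(scope="session")
def benchmark():
    scaffold, truth = make_benchmark(seed=BENCHMARK_SEED)
    ensemble, truth = simulate_trajectory(
        scaffold, truth, n_frames=BENCHMARK_FRAMES, seed=BENCHMARK_SEED
    )
    return scaffold, truth, ensemble


@pytest.fixture(scope="session")
def analysed_benchmark(benchmark):
    """Aligned ensemble + events + water sites for the packaged benchmark."""
    _, truth, ensemble = benchmark
    aligned, fit_rmsd = align_ensemble(ensemble)
    events = detect_all_frames(aligned, detect_hbonds)
    events += detect_all_frames(aligned, detect_salt_bridges)
    events += detect_all_frames(
        aligned, detect_metal_coordination, metal_selection="element CU"
    )
    sites = cluster_water_sites(aligned)
    return {
        "truth": truth,
        "ensemble": ensemble,
        "aligned": aligned,
        "fit_rmsd": fit_rmsd,
        "events": events,
        "sites": sites,
    }
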