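"""Seeded synthetic ensembles with planted, fully known ground truth.

The generator emulates the kind of trajectory the analysis modules are built
for: a rigid scaffold of residue-like groups plus a ligand and metal ions,
per-residue Gaussian positional noise, interactions that toggle on/off as
per-frame Bernoulli draws, hydrophilic sites occupied with set probabilities
by waters whose residue identity exchanges every few frames, and a random
global rigid motion per frame so that superposition is genuinely exercised.
Every random choice flows from one recorded seed; identical seeds give
bit-identical ensembles.

Present/absent partner placement uses the detection cutoff with a 0.5 A
margin on either side, so the detector's ground truth is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PlacementError
from .io import AtomRecord, Ensemble, StructureModel

CLASH_DISTANCE = 1.5


# ---------------------------------------------------------------------------
# residue templates (offsets from the residue centre, A); geometry is
# plausible rather than chemically exact — these are test scaffolds
# ---------------------------------------------------------------------------

_BACKBONE = [
    ("N", (-1.46, 0.0, 0.0)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C", (0.55, 1.40, 0.0)),
    ("O", (1.77, 1.60, 0.0)),
]


def _chain(names, start=(-0.54, -0.78, 1.20), step=(0.0, -1.25, 0.55)):
    out = []
    p = np.array(start)
    for n in names:
        out.append((n, tuple(p)))
        p = p + step
    return out


def _hexagon(center, radius=1.39):
    cx, cy, cz = center
    pts = []
    for k in range(6):
        ang = np.pi / 3 * k
        pts.append((cx + radius * np.cos(ang), cy + radius * np.sin(ang), cz))
    return pts


_SIDECHAINS = {
    "GLY": [],
    "ALA": _chain(["CB"]),
    "SER": _chain(["CB", "OG"]),
    "CYS": _chain(["CB", "SG"]),
    "MET": _chain(["CB", "CG", "SD", "CE"]),
    "ASP": _chain(["CB", "CG"]) + [("OD1", (-1.6, -2.6, 2.0)), ("OD2", (0.4, -3.1, 2.2))],
    "ASN": _chain(["CB", "CG"]) + [("OD1", (-1.6, -2.6, 2.0)), ("ND2", (0.4, -3.1, 2.2))],
    "GLU": _chain(["CB", "CG", "CD"]) + [("OE1", (-1.6, -3.9, 2.5)), ("OE2", (0.4, -4.4, 2.8))],
    "GLN": _chain(["CB", "CG", "CD"]) + [("OE1", (-1.6, -3.9, 2.5)), ("NE2", (0.4, -4.4, 2.8))],
    "LYS": _chain(["CB", "CG", "CD", "CE", "NZ"]),
    "ARG": _chain(["CB", "CG", "CD", "NE"]) + [("NH1", (-1.6, -5.1, 3.2)), ("NH2", (0.5, -5.6, 3.5))],
    "HIS": _chain(["CB", "CG"]) + [("ND1", (-1.5, -2.7, 2.1)), ("NE2", (0.5, -3.2, 2.3))],
    "PHE": _chain(["CB"]) + [
        (n, p) for n, p in zip(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"], _hexagon((-0.5, -3.0, 1.8)))
    ],
}

#: a serotonin-like synthetic ligand: protonated-amine chain N1-C2-C3-C4,
#: an aromatic ring (C5..C10) with hydroxyl O10 and ring nitrogen N6, and
#: hydroxyls O3/O7/O8 so catechol-style contacts can be planted
_LIGAND_TEMPLATE = [
    ("N1", (3.95, -1.30, 0.85)),
    ("C2", (3.10, -0.40, 0.10)),
    ("C3", (1.65, -0.85, 0.05)),
    ("C4", (0.75, 0.10, -0.75)),
    ("C12", (1.10, 1.52, -0.70)),
    ("O3", (3.20, 0.95, 0.60)),
] + [
    (n, p) for n, p in zip(["C5", "C6", "C7", "C8", "C9", "C10"], _hexagon((-0.9, 0.3, -1.4)))
] + [
    ("N6", (-0.9, 2.05, -1.45)),
    ("O10", (-3.05, -0.85, -1.35)),
    ("O7", (-0.15, -2.05, -1.30)),
    ("O8", (-2.45, 1.45, -1.40)),
]


def residue_template(res_name: str) -> list[tuple[str, tuple]]:
    if res_name in _SIDECHAINS:
        return _BACKBONE + _SIDECHAINS[res_name]
    raise KeyError(f"no template for residue {res_name!r}")


# ---------------------------------------------------------------------------
# scaffold specification
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldSpec:
    """Roster of residue-like groups plus geometric constraints.

    residues: (res_name, res_seq, chain) triples drawn from the template set.
    ligand: (res_name, res_seq, chain) placed with the built-in ligand
    template.  metals: (element, res_seq, chain).  pair_distances pins
    |atom_a - atom_b| exactly by translating atom_b's residue; triad pins the
    three pairwise distances of three atoms.
    """

    residues: list[tuple] = field(default_factory=list)
    ligand: tuple | None = None
    metals: list[tuple] = field(default_factory=list)
    pair_distances: list[tuple] = field(default_factory=list)  # (key_a, key_b, d)
    triad: tuple | None = None  # (key1, key2, key3, d12, d13, d23)
    fixed_centers: dict = field(default_factory=dict)  # res_seq -> (x, y, z)
    box_size: float = 40.0
    max_retries: int = 200


def _random_rotation(rng: np.random.Generator, max_deg: float | None = None) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(
        rng.uniform(0.0, max_deg) if max_deg is not None else rng.uniform(0.0, 360.0)
    )
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _find_key(atoms: list[AtomRecord], key) -> int:
    res_seq, name = (key[0], key[1]) if len(key) == 2 else (key[1], key[3])
    for i, a in enumerate(atoms):
        if a.res_seq == res_seq and a.name == name:
            return i
    raise PlacementError(f"constraint references unknown atom {key}")


def _clashes(coords_new, res_seq_new, coords, res_seqs, skip_pairs=()):
    for i, p in enumerate(coords_new):
        d = np.linalg.norm(coords - p, axis=1)
        for j in np.where(d < CLASH_DISTANCE)[0]:
            if res_seqs[j] == res_seq_new:
                continue
            if (res_seq_new, res_seqs[j]) in skip_pairs or (res_seqs[j], res_seq_new) in skip_pairs:
                continue
            return True
    return False


def make_scaffold(spec: ScaffoldSpec, seed: int = 0) -> StructureModel:
    """Deterministically realize a scaffold spec in 3D.

    Residues are dropped into the box one by one with random position and
    orientation under a 1.5 A clash rule, then the pair/triad constraints are
    enforced by rigid translation of the constrained residues.  Bounded
    retries; an unrealizable geometry raises :class:`PlacementError`.
    """
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 1

    def place_group(names_offsets, res_name, res_seq, chain, element_of):
        nonlocal serial, atoms
        offsets = np.array([o for _, o in names_offsets], dtype=float)
        existing = np.array([a.coords for a in atoms]) if atoms else np.empty((0, 3))
        existing_seqs = [a.res_seq for a in atoms]
        fixed = spec.fixed_centers.get(res_seq)
        for _ in range(spec.max_retries):
            center = (
                np.asarray(fixed, dtype=float)
                if fixed is not None
                else rng.uniform(5.0, spec.box_size - 5.0, size=3)
            )
            rot = _random_rotation(rng)
            coords = offsets @ rot.T + center
            if len(existing) == 0 or not _clashes(coords, res_seq, existing, existing_seqs):
                for (name, _), xyz in zip(names_offsets, coords):
                    atoms.append(
                        AtomRecord(serial, name, element_of(name), res_name, res_seq, chain, xyz)
                    )
                    serial += 1
                return
        raise PlacementError(f"cannot place {res_name}{res_seq} without clashes")

    def aa_element(name):
        return name[0] if name[0] in "NOCS" else name[0]

    for res_name, res_seq, chain in spec.residues:
        place_group(residue_template(res_name), res_name, res_seq, chain, aa_element)
    if spec.ligand is not None:
        res_name, res_seq, chain = spec.ligand
        place_group(_LIGAND_TEMPLATE, res_name, res_seq, chain, aa_element)
    for element, res_seq, chain in spec.metals:
        place_group([(element, (0.0, 0.0, 0.0))], element, res_seq, chain, lambda n: element)

    def translate_residue(res_seq, shift):
        for a in atoms:
            if a.res_seq == res_seq:
                a.coords = a.coords + shift

    def check_constraint_ok(ia, ib, skip):
        coords = np.array([a.coords for a in atoms])
        seqs = [a.res_seq for a in atoms]
        mask = [k for k, a in enumerate(atoms) if a.res_seq == atoms[ib].res_seq]
        others = np.array([coords[k] for k in range(len(atoms)) if atoms[k].res_seq != atoms[ib].res_seq])
        other_seqs = [seqs[k] for k in range(len(atoms)) if atoms[k].res_seq != atoms[ib].res_seq]
        return not _clashes(coords[mask], atoms[ib].res_seq, others, other_seqs, skip)

    for key_a, key_b, d in spec.pair_distances:
        ia = _find_key(atoms, key_a)
        ib = _find_key(atoms, key_b)
        pa = atoms[ia].coords
        u = atoms[ib].coords - pa
        norm = np.linalg.norm(u)
        u = u / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        placed = False
        skip = {(atoms[ia].res_seq, atoms[ib].res_seq)}
        for attempt in range(spec.max_retries):
            target = pa + d * u
            translate_residue(atoms[ib].res_seq, target - atoms[ib].coords)
            if d >= CLASH_DISTANCE and check_constraint_ok(ia, ib, skip):
                placed = True
                break
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
        if not placed:
            raise PlacementError(
                f"cannot satisfy distance {d} A between {key_a} and {key_b}"
            )

    if spec.triad is not None:
        key1, key2, key3, d12, d13, d23 = spec.triad
        i1 = _find_key(atoms, key1)
        i2 = _find_key(atoms, key2)
        i3 = _find_key(atoms, key3)
        x3 = (d12**2 + d13**2 - d23**2) / (2 * d12)
        y3sq = d13**2 - x3**2
        if y3sq < 0:
            raise PlacementError("triad distances violate the triangle inequality")
        local = np.array([[0.0, 0.0, 0.0], [d12, 0.0, 0.0], [x3, np.sqrt(y3sq), 0.0]])
        rot = _random_rotation(rng)
        p1 = atoms[i1].coords
        targets = local @ rot.T + p1
        translate_residue(atoms[i2].res_seq, targets[1] - atoms[i2].coords)
        translate_residue(atoms[i3].res_seq, targets[2] - atoms[i3].coords)

    return StructureModel(atoms, model_id=1, provenance=f"synthetic scaffold seed={seed}")


# ---------------------------------------------------------------------------
# planted truth and trajectory simulation
# ---------------------------------------------------------------------------


@dataclass
class PlantedSite:
    """A hydrophilic site the generator will populate."""

    label: str
    centroid: np.ndarray
    occupancy: float  # per-frame Bernoulli probability
    base_res_seq: int
    exchange_period: int = 10  # frames between water-identity swaps
    n_identities: int = 4
    jitter_radius: float = 0.4  # < 0.5 * link_cutoff keeps the site compact

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass
class PlantedInteraction:
    """An interaction toggled per frame: the partner atom is placed at
    ``on_distance`` (inside the detection cutoff, 0.5 A margin) when present
    and ``off_distance`` (outside) when absent."""

    kind: str
    atom_a: tuple  # anchor key (res_seq, name) or full 4-tuple
    atom_b: tuple  # partner key; this atom is moved
    p: float
    on_distance: float
    off_distance: float
    direction: tuple | None = None  # placement direction; default: scaffold axis

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            self.direction = tuple(d / np.linalg.norm(d))


@dataclass
class PlantedTruth:
    """Everything the generator plants, recorded for recovery tests."""

    sites: list[PlantedSite] = field(default_factory=list)
    interactions: list[PlantedInteraction] = field(default_factory=list)
    noise_sigma: float = 0.05
    per_residue_sigma: dict = field(default_factory=dict)
    rigid_max_rot_deg: float = 15.0
    rigid_max_trans: float = 3.0
    rigid_jitter: bool = True
    path_nodes: list[str] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "per_residue_sigma": {str(k): v for k, v in self.per_residue_sigma.items()},
            "rigid_jitter": self.rigid_jitter,
            "rigid_max_rot_deg": self.rigid_max_rot_deg,
            "rigid_max_trans": self.rigid_max_trans,
            "sites": [
                {
                    "label": s.label,
                    "centroid": [float(x) for x in s.centroid],
                    "occupancy": s.occupancy,
                    "exchange_period": s.exchange_period,
                }
                for s in self.sites
            ],
            "interactions": [
                {
                    "kind": i.kind,
                    "atom_a": list(i.atom_a),
                    "atom_b": list(i.atom_b),
                    "p": i.p,
                    "on_distance": i.on_distance,
                    "off_distance": i.off_distance,
                }
                for i in self.interactions
            ],
            "path_nodes": list(self.path_nodes),
        }


def _sphere_jitter(rng: np.random.Generator, radius: float) -> np.ndarray:
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    return u * radius * rng.uniform() ** (1.0 / 3.0)


def simulate_trajectory(
    model: StructureModel,
    truth: PlantedTruth,
    n_frames: int,
    frame_interval_ps: float = 2.0,
    seed: int | None = None,
) -> tuple[Ensemble, PlantedTruth]:
    """Simulate an ensemble from a scaffold under the planted truth.

    Per frame: per-residue Gaussian noise; each planted interaction's partner
    placed on/off its cutoff by a Bernoulli(p) draw; each site populated by a
    Bernoulli(occupancy) water within ``jitter_radius`` of the centroid, the
    water's residue id rotating every ``exchange_period`` frames; finally a
    random global rigid transform (rotation <= rigid_max_rot_deg, translation
    <= rigid_max_trans per axis) so downstream alignment is load-bearing.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if seed is not None:
        truth.seed = seed
    rng = np.random.default_rng(truth.seed if truth.seed is not None else 0)

    base = model.coords
    n_atoms = len(model.atoms)
    sigma = np.array(
        [
            truth.per_residue_sigma.get(a.res_seq, truth.noise_sigma)
            for a in model.atoms
        ]
    )
    ipairs = [
        (_find_key(model.atoms, pi.atom_a), _find_key(model.atoms, pi.atom_b), pi)
        for pi in truth.interactions
    ]
    dirs = []
    for ia, ib, pi in ipairs:
        if pi.direction is not None:
            dirs.append(np.asarray(pi.direction))
            continue
        u = base[ib] - base[ia]
        norm = np.linalg.norm(u)
        dirs.append(u / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0]))

    frames = []
    for f in range(n_frames):
        coords = base + rng.normal(size=(n_atoms, 3)) * sigma[:, None]
        for (ia, ib, pi), u in zip(ipairs, dirs):
            d = pi.on_distance if rng.random() < pi.p else pi.off_distance
            coords[ib] = coords[ia] + d * u

        water_atoms = []
        wserial = 90000
        for s in truth.sites:
            present = rng.random() < s.occupancy
            jitter = _sphere_jitter(rng, s.jitter_radius)
            if not present:
                continue
            res_seq = s.base_res_seq + (f // s.exchange_period) % s.n_identities
            water_atoms.append(
                AtomRecord(wserial, "O", "O", "HOH", res_seq, "W", s.centroid + jitter)
            )
            wserial += 1

        if truth.rigid_jitter:
            rot = _random_rotation(rng, truth.rigid_max_rot_deg)
            trans = rng.uniform(-truth.rigid_max_trans, truth.rigid_max_trans, size=3)
            center = coords.mean(axis=0)
            coords = (coords - center) @ rot.T + center + trans
            for w in water_atoms:
                w.coords = (w.coords - center) @ rot.T + center + trans

        frame_atoms = [
            AtomRecord(
                a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain, coords[i]
            )
            for i, a in enumerate(model.atoms)
        ]
        frames.append(
            StructureModel(frame_atoms + water_atoms, model_id=f + 1, provenance="synthetic")
        )

    return Ensemble(frames, frame_interval=frame_interval_ps), truth


# ---------------------------------------------------------------------------
# packaged benchmark: the full recognition-path cast
# ---------------------------------------------------------------------------

BENCHMARK_PATH_DIRECT = [
    "SRO:N1", "ASP1025", "HIS1026", "CU3052", "CYS1021", "HIS1022", "CU3048",
]
BENCHMARK_PATH_BRIDGED_TAIL = ["MET1031", "GLU1032"]  # then ...WB...CU3047


def benchmark_scaffold_spec() -> ScaffoldSpec:
    """The packaged benchmark cast: an amine ligand in an acidic cavity, a
    mononuclear copper and a copper cluster, wired so that both the direct
    and the water-bridged recognition routes exist."""
    chain = "A"
    residues = [
        ("ASP", 1025, chain),
        ("HIS", 1026, chain),
        ("GLU", 935, chain),
        ("LYS", 938, chain),
        ("GLU", 272, chain),
        ("ASN", 271, chain),
        ("GLU", 232, chain),
        ("ASP", 230, chain),
        ("ASP", 206, chain),
        ("ARG", 239, chain),
        ("PHE", 209, chain),
        ("CYS", 1021, chain),
        ("HIS", 1022, chain),
        ("MET", 1031, chain),
        ("GLU", 1032, chain),
    ]
    # the recognition-path cast sits on a spaced corridor and the cavity
    # residues on a separate grid; only orientations are randomized, which
    # keeps incidental cross-contacts rare without sacrificing variability
    fixed_centers = {
        2001: (10.0, 30.0, 30.0),  # ligand
        1025: (18.0, 30.0, 30.0),
        1026: (25.0, 30.0, 30.0),
        1021: (33.0, 30.0, 30.0),
        1022: (40.0, 30.0, 30.0),
        1031: (29.0, 38.0, 30.0),
        1032: (29.0, 46.0, 30.0),
        935: (8.0, 10.0, 30.0),
        938: (15.0, 10.0, 30.0),
        272: (22.0, 10.0, 30.0),
        271: (29.0, 10.0, 30.0),
        232: (36.0, 10.0, 30.0),
        230: (43.0, 10.0, 30.0),
        206: (8.0, 10.0, 40.0),
        239: (15.0, 10.0, 40.0),
        209: (22.0, 10.0, 40.0),
        3052: (29.0, 30.0, 36.0),  # base positions only; re-placed per frame
        3048: (40.0, 30.0, 36.0),
    }
    # only static relationships are constrained here; the atoms of the
    # recognition path itself are (re)placed per frame by the planted
    # interactions, so their base positions need no pinning
    pairs = [
        ((1032, "OE2"), (3047, "CU"), 5.00),  # bridged by a water site
        ((935, "OE1"), (938, "NZ"), 2.70),  # salt bridge Glu...Lys
    ]
    return ScaffoldSpec(
        residues=residues,
        ligand=("SRO", 2001, chain),
        metals=[("CU", 3047, chain), ("CU", 3048, chain), ("CU", 3052, chain)],
        pair_distances=pairs,
        fixed_centers=fixed_centers,
        box_size=60.0,
    )


def _benchmark_candidate(scaffold_seed, seed, site_occupancies, exchange_period, include_bridge):
    scaffold = make_scaffold(benchmark_scaffold_spec(), seed=scaffold_seed)
    n1 = scaffold.find_atom((2001, "N1")).coords
    oe2 = scaffold.find_atom((1032, "OE2")).coords
    cu3047 = scaffold.find_atom((3047, "CU")).coords

    # directions around the amine keep the three sites >= 4.5 A apart
    offsets = np.array([[3.0, 0.0, 0.0], [-1.5, 3.3, 0.0], [-1.5, -3.3, 0.0]])
    sites = [
        PlantedSite(
            label=f"site{i+1}",
            centroid=n1 + off,
            occupancy=p,
            base_res_seq=2300 + 100 * i,
            exchange_period=exchange_period,
        )
        for i, (off, p) in enumerate(zip(offsets, site_occupancies))
    ]
    if include_bridge:
        # the bridging site sits on the Glu1032(OE2)..Cu3047 axis: H-bond to
        # the carboxylate on one side, coordination distance to the copper on
        # the other
        bridge_centroid = oe2 + (cu3047 - oe2) * (2.6 / np.linalg.norm(cu3047 - oe2))
        sites.append(
            PlantedSite(label="bridge", centroid=bridge_centroid, occupancy=1.0,
                        base_res_seq=2700, exchange_period=exchange_period)
        )

    # ordering matters: each partner atom is placed relative to its anchor's
    # current position, so Cu3052 is positioned before atoms placed off it.
    # The three groups bound to Cu3052 sit 120 deg apart so that no pair of
    # them falls inside the hydrogen-bond cutoff by construction.
    s3 = np.sqrt(3.0) / 2.0
    interactions = [
        PlantedInteraction("hbond", (2001, "N1"), (1025, "OD2"), 1.0, 2.70, 4.5),
        PlantedInteraction("metal_coord", (1026, "NE2"), (3052, "CU"), 1.0, 2.10, 4.0,
                           direction=(1.0, 0.0, 0.0)),
        PlantedInteraction("metal_coord", (3052, "CU"), (1021, "SG"), 1.0, 2.20, 4.0,
                           direction=(0.5, s3, 0.0)),
        PlantedInteraction("metal_coord", (3052, "CU"), (1031, "SD"), 1.0, 2.50, 4.0,
                           direction=(0.5, -s3, 0.0)),
        PlantedInteraction("metal_coord", (1022, "ND1"), (3048, "CU"), 1.0, 2.10, 4.0,
                           direction=(0.0, 0.0, 1.0)),
        PlantedInteraction("salt_bridge", (935, "OE1"), (938, "NZ"), 1.0, 2.70, 5.0),
    ]
    truth = PlantedTruth(
        sites=sites,
        interactions=interactions,
        noise_sigma=0.05,
        path_nodes=list(BENCHMARK_PATH_DIRECT),
        seed=seed,
    )
    return scaffold, truth


def _planted_topology_ok(scaffold, truth, include_bridge) -> bool:
    """Check, on a noiseless frame, that detectors recover exactly the
    planted recognition topology (no incidental shortcut contacts)."""
    from copy import deepcopy

    from . import graph as graphmod
    from .interactions import (
        detect_all_frames,
        detect_hbonds,
        detect_metal_coordination,
        detect_salt_bridges,
    )
    from .waters import cluster_water_sites

    check = deepcopy(truth)
    check.noise_sigma = 0.0
    check.per_residue_sigma = {}
    check.rigid_jitter = False
    for s in check.sites:
        s.occupancy = 1.0
        s.jitter_radius = 0.0
    ens, _ = simulate_trajectory(scaffold, check, n_frames=1, seed=0)
    events = detect_all_frames(ens, detect_hbonds)
    events += detect_all_frames(ens, detect_salt_bridges)
    events += detect_all_frames(ens, detect_metal_coordination, metal_selection="element CU")
    sites = cluster_water_sites(ens)
    g = graphmod.build_graph(ens, events, sites, occ_min=50.0)
    direct = graphmod.find_path(g, "SRO:N1", ["CU3048"])
    if direct is None or direct.nodes != BENCHMARK_PATH_DIRECT:
        return False
    if include_bridge:
        bridged = graphmod.find_path(g, "SRO:N1", ["CU3047"])
        expected_head = BENCHMARK_PATH_DIRECT[:4] + BENCHMARK_PATH_BRIDGED_TAIL
        if (
            bridged is None
            or bridged.hops != 7
            or bridged.nodes[:6] != expected_head
            or not bridged.nodes[6].startswith("WS")
            or bridged.nodes[7] != "CU3047"
        ):
            return False
    return True


def make_benchmark(
    seed: int = 0,
    site_occupancies: tuple = (1.0, 0.85, 0.5),
    exchange_period: int = 10,
    include_bridge: bool = True,
) -> tuple[StructureModel, PlantedTruth]:
    """Scaffold + truth for the standard planted-recovery benchmark.

    Three hydrophilic sites near the ligand amine with occupancies
    ``site_occupancies`` and centroid separations >= 4.5 A; always-on
    interactions wiring the direct ligand-to-cluster path and (optionally)
    the water-bridged Glu-to-cluster route.  Random residue placement can
    create incidental contacts that would make the planted path ambiguous,
    so candidate scaffolds are verified on a noiseless frame and re-drawn
    (deterministically from ``seed``) until the detectors recover exactly
    the planted topology.
    """
    for attempt in range(50):
        scaffold_seed = (seed * 1009 + attempt) % (2**31 - 1)
        try:
            scaffold, truth = _benchmark_candidate(
                scaffold_seed, seed, site_occupancies, exchange_period, include_bridge
            )
        except PlacementError:
            continue
        if _planted_topology_ok(scaffold, truth, include_bridge):
            return scaffold, truth
    raise PlacementError("could not realize an unambiguous benchmark scaffold")


def make_rmsf_benchmark(seed: int = 0, sigma: float = 0.5):
    """Scaffold + truth for RMSF recovery: a mobile 7-residue helix
    (931-937) with per-residue noise ``sigma`` inside an otherwise fixed
    stretch of residues 925-943."""
    chain = "A"
    residues = [("ALA", i, chain) for i in range(925, 944)]
    spec = ScaffoldSpec(residues=residues, box_size=55.0)
    scaffold = make_scaffold(spec, seed=seed)
    mobile = range(931, 938)
    truth = PlantedTruth(
        noise_sigma=0.0,
        per_residue_sigma={i: sigma for i in mobile},
        rigid_jitter=True,
        seed=seed,
    )
    return scaffold, truth
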