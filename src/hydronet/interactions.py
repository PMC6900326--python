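"""Geometric interaction detection and occupancy-frequency statistics.

Hydrogen bonds are scored on heavy-atom donor-acceptor distance alone
(default 3.5 A): trajectory frames stripped to heavy atoms and crystal
structures carry no usable hydrogens, so an angle term is not applicable.
Salt bridges pair carboxylate oxygens with protonated amine/guanidinium
nitrogens (4.0 A), metal coordination pairs a metal with any N/O/S (3.0 A),
and T-shaped aromatic stacking is a centroid-distance plus inter-plane-angle
window.  The occupation frequency (O.F.) of an interaction key is the
percentage of analysed frames in which at least one event with that key is
present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    AtomNotFoundError,
    DegenerateRingError,
    DegenerateTorsionError,
)
from .io import (
    AtomKey,
    AtomRecord,
    Selection,
    StructureModel,
    STANDARD_AA,
    select,
)

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionEvent:
    """One detected contact in one frame; ``extra`` carries the ring angle
    for T-shaped stacking events."""

    kind: str  # hbond | salt_bridge | metal_coord | pi_T
    atom_a: AtomKey
    atom_b: AtomKey
    distance: float
    frame: int = 0
    extra: float | None = None


@dataclass(frozen=True)
class OccupancyRecord:
    """Occupation frequency of one interaction key over a frame range."""

    key: object
    n_present: int
    n_total: int

    @property
    def of_percent(self) -> float:
        return 100.0 * self.n_present / self.n_total


@dataclass
class TorsionSpec:
    """Named dihedral over four ordered atom keys (e.g. a ligand chi1)."""

    label: str
    atoms: Sequence[AtomKey]

    def __post_init__(self):
        if len(self.atoms) != 4 or len({tuple(a) for a in self.atoms}) != 4:
            raise ValueError("a torsion needs four distinct atoms")


# donor/acceptor roles for the residues this package routinely meets; the
# table is deliberately config-overridable rather than exhaustive.
_DEFAULT_ROLES: dict[tuple[str, str], str] = {}


def _add_roles(res: str, donors=(), acceptors=(), both=()):
    for n in donors:
        _DEFAULT_ROLES[(res, n)] = "donor"
    for n in acceptors:
        _DEFAULT_ROLES[(res, n)] = "acceptor"
    for n in both:
        _DEFAULT_ROLES[(res, n)] = "both"


for _res in STANDARD_AA:
    _add_roles(_res, donors=("N",), acceptors=("O", "OXT"))
_add_roles("ASP", acceptors=("OD1", "OD2"))
_add_roles("GLU", acceptors=("OE1", "OE2"))
_add_roles("ASN", donors=("ND2",), acceptors=("OD1",))
_add_roles("GLN", donors=("NE2",), acceptors=("OE1",))
_add_roles("LYS", donors=("NZ",))
_add_roles("ARG", donors=("NE", "NH1", "NH2"))
_add_roles("HIS", both=("ND1", "NE2"))
_add_roles("SER", both=("OG",))
_add_roles("THR", both=("OG1",))
_add_roles("TYR", both=("OH",))
_add_roles("TRP", donors=("NE1",))
_add_roles("CYS", both=("SG",))
_add_roles("MET", acceptors=("SD",))

ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
BASIC_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}
HIS_BASIC_ATOMS = {("HIS", "ND1"), ("HIS", "NE2")}


@dataclass
class DonorAcceptorTable:
    """Role lookup for hydrogen-bond detection.

    Water oxygens are both donor and acceptor; polar atoms (N/O) of residues
    absent from the table — ligands, cofactors — default to `both` when
    ``het_polar_both`` is set, since their protonation is not modelled.
    """

    roles: dict = field(default_factory=lambda: dict(_DEFAULT_ROLES))
    het_polar_both: bool = True

    def role_of(self, atom: AtomRecord) -> str | None:
        if atom.is_water():
            return "both" if atom.element == "O" else None
        role = self.roles.get((atom.res_name, atom.name))
        if role is not None:
            return role
        if (
            self.het_polar_both
            and atom.res_name not in STANDARD_AA
            and atom.element in ("N", "O")
            and not atom.is_metal()
        ):
            return "both"
        return None


# ---------------------------------------------------------------------------
# scalar measurements
# ---------------------------------------------------------------------------


def _require_atom(model: StructureModel, key) -> AtomRecord:
    a = model.find_atom(key)
    if a is None:
        raise AtomNotFoundError(f"atom {key} not found in model {model.model_id}")
    return a


def measure_distance(model: StructureModel, a, b) -> float:
    """Euclidean distance (A) between two atoms given by key."""
    pa = _require_atom(model, a).coords
    pb = _require_atom(model, b).coords
    return float(np.linalg.norm(pa - pb))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees, IUPAC: cis=0, trans=+/-180) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateTorsionError("three consecutive torsion atoms are collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def measure_torsion(model: StructureModel, spec: TorsionSpec) -> float:
    """Dihedral (degrees in (-180, 180]) defined by a :class:`TorsionSpec`."""
    pts = [_require_atom(model, k).coords for k in spec.atoms]
    return dihedral(*pts)


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------


def _sorted_pair(ka: AtomKey, kb: AtomKey) -> tuple[AtomKey, AtomKey]:
    return (ka, kb) if ka <= kb else (kb, ka)


def _same_residue(a: AtomRecord, b: AtomRecord) -> bool:
    return (a.chain, a.res_seq, a.res_name) == (b.chain, b.res_seq, b.res_name)


def _peptide_12_13(a: AtomRecord, b: AtomRecord) -> bool:
    """Backbone pairs 1-2/1-3 bonded through the peptide link i -> i+1."""
    if a.chain != b.chain or abs(a.res_seq - b.res_seq) != 1:
        return False
    lo, hi = (a, b) if a.res_seq < b.res_seq else (b, a)
    return lo.name in ("C", "O", "CA") and hi.name in ("N", "CA")


def _pair_events(
    kind: str,
    group_a: list[AtomRecord],
    group_b: list[AtomRecord],
    d_max: float,
    frame: int,
    exclude_same_residue: bool = True,
    exclude_peptide: bool = False,
) -> list[InteractionEvent]:
    """Distance-cutoff pairing of two atom groups via a KD-tree."""
    if not group_a or not group_b:
        return []
    ca = np.array([a.coords for a in group_a])
    cb = np.array([b.coords for b in group_b])
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), r=d_max)
    seen = {}
    for i, js in enumerate(pairs):
        for j in js:
            a, b = group_a[i], group_b[j]
            if a.key == b.key:
                continue
            if exclude_same_residue and _same_residue(a, b):
                continue
            if exclude_peptide and _peptide_12_13(a, b):
                continue
            ka, kb = _sorted_pair(a.key, b.key)
            d = float(np.linalg.norm(a.coords - b.coords))
            if (kind, ka, kb) not in seen:
                seen[(kind, ka, kb)] = InteractionEvent(kind, ka, kb, d, frame)
    return sorted(seen.values(), key=lambda e: (e.atom_a, e.atom_b))


def detect_hbonds(
    model: StructureModel,
    table: DonorAcceptorTable | None = None,
    d_max: float = 3.5,
    frame: int = 0,
) -> list[InteractionEvent]:
    """Donor-acceptor heavy-atom pairs within ``d_max``, sorted by atom keys.

    Intra-residue pairs and 1-2/1-3 pairs across the peptide bond are
    excluded; water oxygens act as donor and acceptor.
    """
    table = table or DonorAcceptorTable()
    donors, acceptors = [], []
    for a in model.atoms:
        role = table.role_of(a)
        if role in ("donor", "both"):
            donors.append(a)
        if role in ("acceptor", "both"):
            acceptors.append(a)
    return _pair_events(
        "hbond", donors, acceptors, d_max, frame, exclude_peptide=True
    )


def detect_salt_bridges(
    model: StructureModel,
    d_max: float = 4.0,
    include_his: bool = False,
    frame: int = 0,
) -> list[InteractionEvent]:
    """Carboxylate-O to basic-N contacts within ``d_max`` (one event per pair)."""
    basic = BASIC_ATOMS | (HIS_BASIC_ATOMS if include_his else set())
    acid_atoms = [a for a in model.atoms if (a.res_name, a.name) in ACIDIC_ATOMS]
    base_atoms = [a for a in model.atoms if (a.res_name, a.name) in basic]
    return _pair_events("salt_bridge", acid_atoms, base_atoms, d_max, frame)


def detect_metal_coordination(
    model: StructureModel,
    metal_selection: Selection | str,
    d_max: float = 3.0,
    frame: int = 0,
) -> list[InteractionEvent]:
    """Metal to N/O/S contacts within ``d_max``; water oxygens count, which
    is what makes metal...water bridges visible."""
    metals = select(model, metal_selection)
    if not metals:
        raise ValueError("metal selection matches no atoms")
    metal_keys = {m.key for m in metals}
    partners = [
        a for a in model.atoms if a.element in ("N", "O", "S") and a.key not in metal_keys
    ]
    return _pair_events("metal_coord", metals, partners, d_max, frame)


def _ring_plane(coords: np.ndarray):
    centroid = coords.mean(axis=0)
    _, s, vt = np.linalg.svd(coords - centroid)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise DegenerateRingError("ring atoms are collinear; no plane defined")
    return centroid, vt[2]  # normal = least-variance direction


def detect_pi_T(
    model: StructureModel,
    ring_a: Sequence,
    ring_b: Sequence,
    d_window: tuple[float, float] = (4.0, 7.0),
    angle_window: tuple[float, float] = (60.0, 120.0),
    frame: int = 0,
) -> InteractionEvent | None:
    """T-shaped aromatic stacking test between two rings given as atom keys.

    Fires when the centroid separation lies in ``d_window`` and the angle
    between the ring planes lies in ``angle_window`` (the plane angle is
    reported in [0, 90]; the window may be stated in either convention).
    """
    ca = np.array([_require_atom(model, k).coords for k in ring_a])
    cb = np.array([_require_atom(model, k).coords for k in ring_b])
    if len(ca) < 5 or len(cb) < 5:
        raise ValueError("each ring needs >= 5 atoms")
    cen_a, n_a = _ring_plane(ca)
    cen_b, n_b = _ring_plane(cb)
    d = float(np.linalg.norm(cen_a - cen_b))
    cosang = abs(float(n_a @ n_b)) / (np.linalg.norm(n_a) * np.linalg.norm(n_b))
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))  # in [0, 90]
    lo, hi = angle_window
    in_angle = lo <= ang <= hi or lo <= 180.0 - ang <= hi
    if d_window[0] <= d <= d_window[1] and in_angle:
        return InteractionEvent(
            "pi_T", tuple(ring_a[0]), tuple(ring_b[0]), d, frame, extra=ang
        )
    return None


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------


def pair_key(event: InteractionEvent):
    """Default grouping: one key per (kind, atom pair)."""
    return (event.kind, event.atom_a, event.atom_b)


def residue_pair_key(event: InteractionEvent):
    """Residue-level grouping: Asp1025 OD1 or OD2 count as one partner."""
    ra = (event.atom_a[0], event.atom_a[1], event.atom_a[2])
    rb = (event.atom_b[0], event.atom_b[1], event.atom_b[2])
    return (event.kind,) + tuple(sorted((ra, rb)))


def occupancy(
    events: Iterable[InteractionEvent],
    key_fn: Callable[[InteractionEvent], object] = pair_key,
    frame_range: Sequence[int] | None = None,
    n_frames: int | None = None,
) -> list[OccupancyRecord]:
    """Occupation frequency per interaction key.

    ``frame_range`` is the set of analysed frame indices (default: all frames
    0..n_frames-1, with ``n_frames`` inferred from the events if not given).
    A key is present in a frame if at least one of its events occurs there.
    """
    events = list(events)
    if frame_range is None:
        if n_frames is None:
            n_frames = (max((e.frame for e in events), default=-1)) + 1
        frame_range = range(n_frames)
    frame_set = set(frame_range)
    if not frame_set:
        raise ValueError("frame_range is empty")
    present: dict[object, set] = {}
    for e in events:
        if e.frame in frame_set:
            present.setdefault(key_fn(e), set()).add(e.frame)
    records = [
        OccupancyRecord(key=k, n_present=len(fr), n_total=len(frame_set))
        for k, fr in present.items()
    ]
    records.sort(key=lambda r: (-r.of_percent, repr(r.key)))
    return records


def detect_all_frames(
    ensemble,
    detector: Callable[..., list[InteractionEvent]],
    **kwargs,
) -> list[InteractionEvent]:
    """Run a per-model detector over every frame of an ensemble."""
    events: list[InteractionEvent] = []
    for i, frame in enumerate(ensemble.frames):
        events.extend(detector(frame, frame=i, **kwargs))
    return events
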