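"""Coordinate I/O, atom records, selections and frame ensembles.

A multi-MODEL PDB file maps onto an :class:`Ensemble`: one
:class:`StructureModel` per MODEL block, all sharing the same non-water atom
table while the water complement may differ frame to frame (solvent
identities exchange during a simulation).  Residue and atom numbering is
preserved verbatim from the input file; nothing is ever renumbered.

Waters are treated oxygen-only by default throughout the package: frames
converted to a three-site water model may or may not carry hydrogens, and
crystal structures never do, so analyses that must treat both uniformly key
on the water oxygen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    EnsembleConsistencyError,
    SelectionSyntaxError,
)

DEFAULT_WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

_METAL_ELEMENTS = frozenset(
    {"CU", "ZN", "FE", "MN", "NI", "CO", "MG", "NA", "K", "CA", "MO", "W"}
)

#: atom identity used everywhere downstream: (chain, res_seq, res_name, name)
AtomKey = tuple


def atom_key(atom: "AtomRecord") -> AtomKey:
    return (atom.chain, atom.res_seq, atom.res_name, atom.name)


@dataclass
class AtomRecord:
    """One atom of one model; coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    coords: np.ndarray
    occupancy_field: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")

    @property
    def key(self) -> AtomKey:
        return atom_key(self)

    def is_water(self, water_resnames=DEFAULT_WATER_RESNAMES) -> bool:
        return self.res_name in water_resnames

    def is_metal(self) -> bool:
        return self.element in _METAL_ELEMENTS and self.res_name not in STANDARD_AA


@dataclass
class StructureModel:
    """One frame of a trajectory, or one crystal structure."""

    atoms: list[AtomRecord]
    model_id: int = 1
    provenance: str = ""

    def __post_init__(self):
        if self.model_id < 1:
            raise ValueError("model_id must be >= 1")
        self._index = None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def _key_index(self) -> dict:
        if self._index is None:
            self._index = {a.key: i for i, a in enumerate(self.atoms)}
        return self._index

    def find_atom(self, key: AtomKey) -> AtomRecord | None:
        """Look up an atom by full or partial key.

        A 4-tuple is matched exactly; a 3-tuple (chain, res_seq, name) or a
        2-tuple (res_seq, name) falls back to a scan ignoring the omitted
        fields.
        """
        if len(key) == 4:
            i = self._key_index().get(tuple(key))
            if i is not None:
                return self.atoms[i]
            chain, res_seq, _res_name, name = key
        elif len(key) == 3:
            chain, res_seq, name = key
        elif len(key) == 2:
            chain = None
            res_seq, name = key
        else:
            raise ValueError(f"bad atom key {key!r}")
        for a in self.atoms:
            if (
                a.res_seq == res_seq
                and a.name == name
                and (chain is None or a.chain == chain)
            ):
                return a
        return None

    def water_oxygens(self, water_resnames=DEFAULT_WATER_RESNAMES) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if a.is_water(water_resnames) and a.element == "O"
        ]

    def nonwater_keys(self, water_resnames=DEFAULT_WATER_RESNAMES) -> frozenset:
        return frozenset(a.key for a in self.atoms if not a.is_water(water_resnames))

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        atoms = [replace(a, coords=coords[i]) for i, a in enumerate(self.atoms)]
        return StructureModel(atoms, model_id=self.model_id, provenance=self.provenance)


@dataclass
class Ensemble:
    """Ordered frames sharing one non-water atom table.

    ``frame_interval`` is the sampling period in ps (default 2 ps, the
    convention for the trajectories this package analyses); ``t0`` the time
    of the first frame.
    """

    frames: list[StructureModel]
    frame_interval: float = 2.0
    t0: float = 0.0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps."""
        return self.t0 + self.frame_interval * np.arange(self.n_frames)

    def validate(self, water_resnames=DEFAULT_WATER_RESNAMES) -> None:
        """Raise if frames disagree on the non-water atom table."""
        if not self.frames:
            raise EmptyStructureError("ensemble has no frames")
        ref = self.frames[0].nonwater_keys(water_resnames)
        for f in self.frames[1:]:
            keys = f.nonwater_keys(water_resnames)
            if keys != ref:
                diff = sorted(ref ^ keys)
                raise EnsembleConsistencyError(
                    f"frame {f.model_id} disagrees with frame "
                    f"{self.frames[0].model_id} on atom {diff[0]}"
                )

    def frame_at_time(self, t_ps: float) -> int:
        """Index of the frame nearest to ``t_ps``; ties go to the earlier frame."""
        times = self.times
        if t_ps < times[0] - 0.5 * self.frame_interval or t_ps > times[-1] + 0.5 * self.frame_interval:
            raise ValueError(
                f"time {t_ps} ps outside trajectory span [{times[0]}, {times[-1]}] ps"
            )
        d = np.abs(times - t_ps)
        return int(np.argmin(d))  # argmin takes the first (earlier) minimum


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


@dataclass
class Selection:
    """Declarative atom filter; evaluation order is file order (deterministic).

    Waters match oxygen-only by default unless atom names are requested
    explicitly or ``oxygen_only_waters`` is disabled.
    """

    chains: frozenset | None = None
    res_names: frozenset | None = None
    res_seqs: frozenset | None = None
    names: frozenset | None = None
    elements: frozenset | None = None
    water: bool | None = None
    protein: bool | None = None
    backbone: bool = False
    oxygen_only_waters: bool = True
    water_resnames: frozenset = DEFAULT_WATER_RESNAMES

    @classmethod
    def parse(cls, expression: str) -> "Selection":
        """Parse a small `and`-joined expression.

        Clauses: ``chain A`` | ``resname HOH,WAT`` | ``res 10-20,25`` |
        ``name OD1,OD2`` | ``element CU`` | ``water`` | ``not water`` |
        ``protein`` | ``backbone`` | ``all``.
        """
        sel = cls()
        expr = expression.strip()
        if not expr:
            raise SelectionSyntaxError("empty selection expression")
        for clause in re.split(r"\s+and\s+", expr):
            tokens = clause.split()
            if not tokens:
                raise SelectionSyntaxError(f"empty clause in {expression!r}")
            kw = tokens[0].lower()
            args = tokens[1:]
            if kw == "all" and not args:
                continue
            elif kw == "water" and not args:
                sel.water = True
            elif kw == "not" and args == ["water"]:
                sel.water = False
            elif kw == "protein" and not args:
                sel.protein = True
            elif kw == "backbone" and not args:
                sel.backbone = True
            elif kw in ("chain", "resname", "name", "element") and len(args) == 1:
                values = frozenset(v for v in args[0].split(",") if v)
                if not values:
                    raise SelectionSyntaxError(f"no values in clause {clause!r}")
                if kw == "chain":
                    sel.chains = values
                elif kw == "resname":
                    sel.res_names = frozenset(v.upper() for v in values)
                elif kw == "name":
                    sel.names = frozenset(v.upper() for v in values)
                else:
                    sel.elements = frozenset(v.upper() for v in values)
            elif kw == "res" and len(args) == 1:
                seqs = set()
                for part in args[0].split(","):
                    m = _RANGE_RE.match(part)
                    if not m:
                        raise SelectionSyntaxError(f"bad residue range {part!r}")
                    lo = int(m.group(1))
                    hi = int(m.group(2)) if m.group(2) is not None else lo
                    if hi < lo:
                        raise SelectionSyntaxError(f"inverted range {part!r}")
                    seqs.update(range(lo, hi + 1))
                sel.res_seqs = frozenset(seqs)
            else:
                raise SelectionSyntaxError(f"cannot parse clause {clause!r}")
        return sel

    def matches(self, atom: AtomRecord) -> bool:
        is_wat = atom.is_water(self.water_resnames)
        if self.water is not None and is_wat != self.water:
            return False
        if self.protein is not None and (atom.res_name in STANDARD_AA) != self.protein:
            return False
        if self.backbone and not (
            atom.res_name in STANDARD_AA and atom.name in BACKBONE_NAMES
        ):
            return False
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.res_names is not None and atom.res_name not in self.res_names:
            return False
        if self.res_seqs is not None and atom.res_seq not in self.res_seqs:
            return False
        if self.names is not None and atom.name not in self.names:
            return False
        if self.elements is not None and atom.element not in self.elements:
            return False
        if is_wat and self.oxygen_only_waters and self.names is None and atom.element != "O":
            return False
        return True


def select(model: StructureModel, sel: Selection | str) -> list[AtomRecord]:
    """Atoms of ``model`` matching ``sel``, in file order; may be empty."""
    if isinstance(sel, str):
        sel = Selection.parse(sel)
    return [a for a in model.atoms if sel.matches(a)]


def backbone_selection() -> Selection:
    """Default superposition selection: protein backbone heavy atoms."""
    return Selection(protein=True, backbone=True, water=False)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _infer_element(name: str, res_name: str) -> str:
    letters = "".join(c for c in name if c.isalpha())
    if not letters:
        return "X"
    if res_name.upper() == letters.upper() and len(letters) <= 2:
        # single-atom het residues named after the element (CU, ZN, FE ...)
        return letters.upper()
    if name[0].isdigit():
        return letters[0].upper()
    return letters[0].upper()


def read_structure(
    path,
    dialect: str = "pdb",
    water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES,
    frame_interval: float = 2.0,
    t0: float = 0.0,
) -> Ensemble:
    """Read a (multi-MODEL) PDB file into an :class:`Ensemble`.

    One frame per MODEL block (a single frame if the file has no MODEL
    records).  Among altlocs of one atom, the highest-occupancy copy is kept;
    occupancy ties break toward the earliest altloc letter.  Frames are
    ordered by MODEL number regardless of record order in the file.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    water_resnames = frozenset(water_resnames)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc

    frames = []
    for i, model in enumerate(st):
        atoms: list[AtomRecord] = []
        for chain in model:
            for res in chain:
                best: dict[str, gemmi.Atom] = {}
                for atom in res:
                    cur = best.get(atom.name)
                    if cur is None or (atom.occ, -_altloc_rank(atom.altloc)) > (
                        cur.occ,
                        -_altloc_rank(cur.altloc),
                    ):
                        best[atom.name] = atom
                for atom in res:  # preserve file order among kept atoms
                    if best.get(atom.name) is not atom:
                        continue
                    el = atom.element.name.upper()
                    if not el or el == "X":
                        el = _infer_element(atom.name, res.name)
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial,
                            name=atom.name,
                            element=el,
                            res_name=res.name,
                            res_seq=res.seqid.num,
                            chain=chain.name,
                            coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            occupancy_field=atom.occ,
                            b_factor=atom.b_iso,
                        )
                    )
        try:
            num = int(model.num) if hasattr(model, "num") else int(model.name)
        except (TypeError, ValueError):
            num = i + 1
        if atoms:
            frames.append(StructureModel(atoms, model_id=num, provenance=str(path)))

    if not frames:
        raise EmptyStructureError(f"{path} contains no ATOM/HETATM records")
    frames.sort(key=lambda f: f.model_id)
    ens = Ensemble(frames, frame_interval=frame_interval, t0=t0)
    ens.validate(water_resnames)
    return ens


def _altloc_rank(altloc: str) -> int:
    return 0 if not altloc or altloc == "\0" else ord(altloc)


def _format_atom_line(a: AtomRecord) -> str:
    record = "ATOM" if a.res_name in STANDARD_AA else "HETATM"
    if len(a.name) >= 4 or len(a.element) >= 2 or a.name[:1].isdigit():
        name_field = f"{a.name:<4s}"
    else:
        name_field = f" {a.name:<3s}"
    serial = a.serial if 0 <= a.serial <= 99999 else 99999
    return (
        f"{record:<6s}{serial:>5d} {name_field}{'':1s}{a.res_name:>3s} "
        f"{a.chain[:1] or 'A':1s}{a.res_seq:>4d}{'':1s}   "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{a.occupancy_field:6.2f}{a.b_factor:6.2f}          {a.element:>2s}"
    )


def write_structure(ensemble: Ensemble | StructureModel, path) -> None:
    """Write an ensemble as a multi-MODEL PDB (single-model dialect for 1 frame).

    Coordinates are written at 3 decimals, so a write/read round trip
    preserves them to +/-0.001 A and atom identities exactly.
    """
    if isinstance(ensemble, StructureModel):
        ensemble = Ensemble([ensemble])
    if not ensemble.frames:
        raise ValueError("cannot write an empty ensemble")
    path = Path(path)
    multi = ensemble.n_frames > 1
    lines = []
    for f in ensemble.frames:
        if multi:
            lines.append(f"MODEL     {f.model_id:>4d}")
        lines.extend(_format_atom_line(a) for a in f.atoms)
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
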