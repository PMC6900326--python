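"""Trajectory time-series metrics and the consolidated interaction report.

RMSD is computed against a reference frame after alignment; RMSF per residue
is sqrt(<|r - <r>|^2>) over frames averaged over the residue's selected
atoms.  The tracked report mirrors the field's snapshot tables: for each
followed interaction it prints the distance at a handful of snapshot times
plus the whole-trajectory occupation frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentSelectionError
from .interactions import InteractionEvent
from .io import Ensemble, Selection, select
from .waters import WaterSite


@dataclass
class MetricSeries:
    """A per-frame (or per-residue) metric with summary statistics."""

    label: str
    index: np.ndarray  # frame indices or residue numbers
    values: np.ndarray
    times: np.ndarray | None = None  # ps; None for residue-indexed series

    def __post_init__(self):
        self.index = np.asarray(self.index)
        self.values = np.asarray(self.values, dtype=float)
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.values):
                raise ValueError("times and values length mismatch")
            if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")
        if len(self.index) != len(self.values):
            raise ValueError("index and values length mismatch")

    @property
    def summary(self) -> dict:
        return {
            "min": float(self.values.min()),
            "max": float(self.values.max()),
            "mean": float(self.values.mean()),
            "sd": float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0,
        }

    def to_dataframe(self) -> pd.DataFrame:
        data = {"index": self.index, self.label: self.values}
        if self.times is not None:
            data = {"frame": self.index, "time_ps": self.times, self.label: self.values}
        return pd.DataFrame(data)


def _selected_coords(ensemble: Ensemble, sel: Selection | str):
    """Per-frame coordinate stack over the selection's frame-0 atom keys."""
    if isinstance(sel, str):
        sel = Selection.parse(sel)
    ref_atoms = select(ensemble.frames[0], sel)
    if not ref_atoms:
        raise AlignmentSelectionError("selection matches no atoms")
    keys = [a.key for a in ref_atoms]
    stack = np.empty((ensemble.n_frames, len(keys), 3))
    for i, frame in enumerate(ensemble.frames):
        for j, key in enumerate(keys):
            a = frame.find_atom(key)
            if a is None:
                raise AlignmentSelectionError(
                    f"atom {key} missing from frame {frame.model_id}"
                )
            stack[i, j] = a.coords
    return ref_atoms, stack


def rmsd_series(
    aligned: Ensemble,
    sel: Selection | str | None = None,
    reference_frame: int = 0,
    label: str = "rmsd_A",
) -> MetricSeries:
    """Per-frame RMSD (A) over ``sel`` against ``reference_frame``.

    The ensemble is expected to be aligned already; no further fitting is
    applied here.
    """
    sel = sel if sel is not None else Selection(protein=True, backbone=True)
    _, stack = _selected_coords(aligned, sel)
    ref = stack[reference_frame]
    diff = stack - ref
    vals = np.sqrt(np.einsum("fij,fij->f", diff, diff) / stack.shape[1])
    return MetricSeries(
        label=label,
        index=np.arange(aligned.n_frames),
        values=vals,
        times=aligned.times,
    )


def rmsf_per_residue(
    aligned: Ensemble,
    sel: Selection | str | None = None,
    label: str = "rmsf_A",
) -> MetricSeries:
    """Per-residue RMSF (A): per-atom fluctuation about the trajectory mean
    position, averaged over each residue's selected atoms."""
    sel = sel if sel is not None else Selection(protein=True, backbone=True)
    atoms, stack = _selected_coords(aligned, sel)
    mean = stack.mean(axis=0)
    dev = stack - mean
    per_atom = np.sqrt(np.einsum("fij,fij->i", dev, dev) / stack.shape[0])
    residues: dict[tuple, list[int]] = {}
    for j, a in enumerate(atoms):
        residues.setdefault((a.chain, a.res_seq), []).append(j)
    res_ids = sorted(residues)
    vals = np.array([per_atom[residues[r]].mean() for r in res_ids])
    return MetricSeries(
        label=label, index=np.array([r[1] for r in res_ids]), values=vals
    )


@dataclass
class TrackedInteraction:
    """One row of the snapshot report: a ligand atom against a partner atom
    or water site."""

    label: str
    atom_a: tuple
    atom_b: tuple | None = None  # partner atom key...
    site_id: str | None = None  # ...or a water-site label

    def __post_init__(self):
        if (self.atom_b is None) == (self.site_id is None):
            raise ValueError("exactly one of atom_b / site_id must be given")


@dataclass
class ReportSpec:
    """Tracked interactions, snapshot times (ps) and the distance cutoff
    used for the occupancy column."""

    tracked: list[TrackedInteraction] = field(default_factory=list)
    snapshot_times_ps: list[float] = field(default_factory=list)
    d_max: float = 3.5


def tracked_report(
    ensemble: Ensemble,
    events: Sequence[InteractionEvent],
    sites: Sequence[WaterSite],
    spec: ReportSpec,
) -> pd.DataFrame:
    """Snapshot distances plus whole-trajectory O.F. per tracked interaction.

    Snapshot columns use the nearest frame (ties toward the earlier frame).
    For a water-site partner, the distance is to the site's member water in
    that frame (empty cell when the site is vacant); the O.F. counts frames
    in which the partner lies within ``spec.d_max`` of the tracked atom.
    """
    sites_by_id = {s.site_id: s for s in sites}
    snap_frames = [ensemble.frame_at_time(t) for t in spec.snapshot_times_ps]
    rows = []
    for tr in spec.tracked:
        row = {"label": tr.label}
        n_present = 0
        for fi, frame in enumerate(ensemble.frames):
            d = _tracked_distance(frame, fi, tr, sites_by_id)
            if d is not None and d <= spec.d_max:
                n_present += 1
        for t, fi in zip(spec.snapshot_times_ps, snap_frames):
            d = _tracked_distance(ensemble.frames[fi], fi, tr, sites_by_id)
            row[f"t{t:g}ps"] = round(d, 2) if d is not None else None
        row["of_percent"] = 100.0 * n_present / ensemble.n_frames
        rows.append(row)
    return pd.DataFrame(rows)


def _tracked_distance(frame, frame_idx, tr: TrackedInteraction, sites_by_id):
    a = frame.find_atom(tr.atom_a)
    if a is None:
        return None
    if tr.atom_b is not None:
        b = frame.find_atom(tr.atom_b)
        return float(np.linalg.norm(a.coords - b.coords)) if b is not None else None
    site = sites_by_id.get(tr.site_id)
    if site is None:
        return None
    m = site.member_in_frame(frame_idx)
    if m is None:
        return None
    return float(np.linalg.norm(a.coords - m.position))


def events_to_dataframe(events: Sequence[InteractionEvent], frame_interval: float = 2.0, t0: float = 0.0) -> pd.DataFrame:
    """Flat event table for CSV export."""
    rows = []
    for e in events:
        ca, ra, rna, na = e.atom_a
        cb, rb, rnb, nb = e.atom_b
        rows.append(
            {
                "kind": e.kind,
                "chainA": ca,
                "resA": ra,
                "resnameA": rna,
                "atomA": na,
                "chainB": cb,
                "resB": rb,
                "resnameB": rnb,
                "atomB": nb,
                "distance_A": e.distance,
                "frame": e.frame,
                "time_ps": t0 + frame_interval * e.frame,
            }
        )
    return pd.DataFrame(rows)
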