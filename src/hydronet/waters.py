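"""Conserved-water-site detection across a superposed ensemble.

A hydrophilic site is a position in the reference frame that is occupied by
*some* water molecule — not necessarily the same one — in a large fraction
of frames.  Waters are paired to sites with a 1.8 A distance cutoff after
superposition.  The O.F. of a site counts site occupancy, not the identity
of the occupying water: the occupant's residue id is allowed (expected,
even) to exchange over the trajectory, and each site records the distinct
ids it has hosted.

Multi-frame clustering is greedy leader clustering with one refinement pass:
deterministic, O(waters x sites), and auditable — every assignment is within
the link cutoff of the site centroid at the moment of assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interactions import OccupancyRecord
from .io import (
    DEFAULT_WATER_RESNAMES,
    Ensemble,
    Selection,
    StructureModel,
    select,
)

CONSERVED = "conserved"
SEMI_CONSERVED = "semi_conserved"
TRANSIENT = "transient"


@dataclass
class ClusterParams:
    """Knobs of the site detector.

    link_cutoff: superposed-water pairing distance, A (default 1.8).
    min_occupancy_report: sites below this O.F. (%) are dropped from reports.
    conserved_threshold / semi_threshold: O.F. (%) class boundaries; ~100%
    sites are conserved, ~85% sites semi-conserved under the defaults.
    """

    link_cutoff: float = 1.8
    min_occupancy_report: float = 10.0
    conserved_threshold: float = 90.0
    semi_threshold: float = 60.0

    def __post_init__(self):
        if self.link_cutoff <= 0:
            raise ValueError("link_cutoff must be positive")
        if not (0 <= self.semi_threshold <= self.conserved_threshold <= 100):
            raise ValueError("need 0 <= semi_threshold <= conserved_threshold <= 100")


@dataclass
class SiteMember:
    """One water assigned to a site in one frame."""

    frame: int
    water_id: tuple  # (chain, res_seq)
    position: np.ndarray
    distance: float  # to the centroid at assignment time


@dataclass
class WaterSite:
    """A hydrophilic site: centroid (reference frame), per-frame members,
    occupancy and conservation class."""

    site_id: str
    centroid: np.ndarray
    members: list[SiteMember] = field(default_factory=list)
    occupancy: OccupancyRecord | None = None
    conservation_class: str | None = None

    @property
    def of_percent(self) -> float:
        return self.occupancy.of_percent if self.occupancy else 0.0

    @property
    def distinct_water_ids(self) -> list[tuple]:
        return sorted({m.water_id for m in self.members})

    def member_in_frame(self, frame: int) -> SiteMember | None:
        for m in self.members:
            if m.frame == frame:
                return m
        return None


class _Cluster:
    __slots__ = ("centroid", "members", "_sum")

    def __init__(self, position, member):
        self._sum = np.array(position, dtype=float)
        self.members = [member]
        self.centroid = self._sum.copy()

    def add(self, member):
        self.members.append(member)
        self._sum += member.position
        self.centroid = self._sum / len(self.members)

    def remove(self, member):
        self.members.remove(member)
        self._sum -= member.position
        if self.members:
            self.centroid = self._sum / len(self.members)


def _frame_waters(
    frame: StructureModel,
    water_resnames,
    region_atoms: np.ndarray | None,
    region_radius: float,
):
    """Water-oxygen (position, id) list of one frame, optionally restricted
    to a radius around region atoms."""
    out = []
    for a in frame.water_oxygens(water_resnames):
        if region_atoms is not None:
            if np.min(np.linalg.norm(region_atoms - a.coords, axis=1)) > region_radius:
                continue
        out.append((a.coords, (a.chain, a.res_seq)))
    return out


def _assign_frame(waters, clusters, frame_idx, link_cutoff, allow_seed, update):
    """Greedy per-frame assignment with displacement re-queueing."""
    occupant: dict[int, SiteMember] = {}
    pending = list(waters)
    while pending:
        pos, wid = pending.pop(0)
        candidates = []
        for ci, cl in enumerate(clusters):
            d = float(np.linalg.norm(cl.centroid - pos))
            if d <= link_cutoff:
                candidates.append((d, ci))
        candidates.sort()
        placed = False
        for d, ci in candidates:
            cur = occupant.get(ci)
            member = SiteMember(frame_idx, wid, np.array(pos), d)
            if cur is None:
                occupant[ci] = member
                if update:
                    clusters[ci].add(member)
                else:
                    clusters[ci].members.append(member)
                placed = True
                break
            if d < cur.distance:
                # this water is nearer: displace the occupant and re-queue it
                if update:
                    clusters[ci].remove(cur)
                else:
                    clusters[ci].members.remove(cur)
                occupant[ci] = member
                if update:
                    clusters[ci].add(member)
                else:
                    clusters[ci].members.append(member)
                pending.append((cur.position, cur.water_id))
                placed = True
                break
        if not placed and allow_seed:
            member = SiteMember(frame_idx, wid, np.array(pos), 0.0)
            clusters.append(_Cluster(pos, member))
            occupant[len(clusters) - 1] = member


def cluster_water_sites(
    aligned: Ensemble,
    params: ClusterParams | None = None,
    region: Selection | str | None = None,
    region_radius: float = 6.0,
    water_resnames=DEFAULT_WATER_RESNAMES,
) -> list[WaterSite]:
    """Detect hydrophilic sites in an already-superposed ensemble.

    Pass 1 processes waters frame by frame, assigning each to the nearest
    existing site within ``params.link_cutoff`` (at most one water per site
    per frame; the nearer water wins and the displaced one is re-queued),
    else seeding a new site.  Pass 2 freezes the pass-1 centroids and
    re-assigns every water against them; the final centroid is the mean of
    the retained members.  Sites are sorted by occupancy (descending) and
    labelled WS1, WS2, ... deterministically; sites below
    ``min_occupancy_report`` % occupancy are dropped.

    ``region`` restricts the analysis to waters within ``region_radius`` A
    of the selected atoms (binding-site mode), evaluated per frame.
    """
    params = params or ClusterParams()
    per_frame_waters = []
    for frame in aligned.frames:
        region_atoms = None
        if region is not None:
            ratoms = select(frame, region)
            region_atoms = np.array([a.coords for a in ratoms]) if ratoms else np.empty((0, 3))
        per_frame_waters.append(
            _frame_waters(frame, water_resnames, region_atoms, region_radius)
        )

    clusters: list[_Cluster] = []
    for i, waters in enumerate(per_frame_waters):
        _assign_frame(waters, clusters, i, params.link_cutoff, allow_seed=True, update=True)

    # refinement: frozen centroids, fresh assignment, no new sites
    frozen = [cl.centroid.copy() for cl in clusters]
    refined = [_Cluster(c, None) for c in frozen]
    for cl in refined:
        cl.members = []
    for i, waters in enumerate(per_frame_waters):
        _assign_frame(waters, refined, i, params.link_cutoff, allow_seed=False, update=False)

    n_frames = aligned.n_frames
    sites: list[WaterSite] = []
    for cl in refined:
        if not cl.members:
            continue
        centroid = np.mean([m.position for m in cl.members], axis=0)
        frames_present = len({m.frame for m in cl.members})
        occ = OccupancyRecord(key=None, n_present=frames_present, n_total=n_frames)
        sites.append(WaterSite(site_id="", centroid=centroid, members=cl.members, occupancy=occ))

    sites = [s for s in sites if s.of_percent >= params.min_occupancy_report]
    sites.sort(key=lambda s: -s.of_percent)  # stable: seeding order breaks ties
    for rank, s in enumerate(sites, start=1):
        s.site_id = f"WS{rank}"
        s.occupancy = OccupancyRecord(
            key=s.site_id, n_present=s.occupancy.n_present, n_total=n_frames
        )
    return classify_sites(sites, params)


def classify_sites(sites: list[WaterSite], params: ClusterParams | None = None) -> list[WaterSite]:
    """Attach conservation classes by occupancy thresholds."""
    params = params or ClusterParams()
    for s in sites:
        of = s.of_percent
        if of >= params.conserved_threshold:
            s.conservation_class = CONSERVED
        elif of >= params.semi_threshold:
            s.conservation_class = SEMI_CONSERVED
        else:
            s.conservation_class = TRANSIENT
    return sites


def match_waters_between_structures(
    reference: StructureModel,
    other: StructureModel,
    cutoff: float = 1.8,
    water_resnames=DEFAULT_WATER_RESNAMES,
) -> list[tuple[tuple, tuple, float]]:
    """One-to-one pairing of superposed waters between two structures.

    Candidate pairs are sorted by distance; pairs within ``cutoff`` whose
    waters are both still unmatched are accepted greedily.  Returns
    (ref water id, other water id, distance) triples.
    """
    ref_w = [(a.coords, (a.chain, a.res_seq)) for a in reference.water_oxygens(water_resnames)]
    oth_w = [(a.coords, (a.chain, a.res_seq)) for a in other.water_oxygens(water_resnames)]
    pairs = []
    for i, (pa, ida) in enumerate(ref_w):
        for j, (pb, idb) in enumerate(oth_w):
            d = float(np.linalg.norm(pa - pb))
            if d <= cutoff:
                pairs.append((d, i, j))
    pairs.sort()
    used_ref, used_oth = set(), set()
    matches = []
    for d, i, j in pairs:
        if i in used_ref or j in used_oth:
            continue
        used_ref.add(i)
        used_oth.add(j)
        matches.append((ref_w[i][1], oth_w[j][1], d))
    return matches


def sites_to_dataframe(sites: list[WaterSite]):
    """Site report table (one row per site)."""
    import pandas as pd

    rows = []
    for s in sites:
        rows.append(
            {
                "site_id": s.site_id,
                "x": s.centroid[0],
                "y": s.centroid[1],
                "z": s.centroid[2],
                "n_present": s.occupancy.n_present,
                "n_total": s.occupancy.n_total,
                "of_percent": s.of_percent,
                "class": s.conservation_class,
                "distinct_water_ids": ";".join(
                    f"{c}{r}" for c, r in s.distinct_water_ids
                ),
            }
        )
    return pd.DataFrame(rows)
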