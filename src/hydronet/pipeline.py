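"""End-to-end orchestration: align, detect, cluster, graph, report.

``run_full_analysis`` chains the library stages deterministically under one
config and writes the report bundle (CSV/JSON, each embedding the config
hash).  Stage failures propagate with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import graph as graphmod
from .config import AnalysisConfig
from .errors import HydronetError
from .interactions import (
    TorsionSpec,
    detect_all_frames,
    detect_hbonds,
    detect_metal_coordination,
    detect_salt_bridges,
    measure_torsion,
    occupancy,
    residue_pair_key,
)
from .io import Ensemble, read_structure
from .report import (
    ReportSpec,
    TrackedInteraction,
    events_to_dataframe,
    rmsd_series,
    rmsf_per_residue,
    tracked_report,
)
from .superpose import align_ensemble
from .waters import ClusterParams, cluster_water_sites, sites_to_dataframe

log = logging.getLogger("hydronet")


@dataclass
class AnalysisResult:
    """In-memory bundle of everything a full run produced."""

    aligned: Ensemble
    fit_rmsd: object
    events: list
    occupancy_records: list
    sites: list
    graph: object | None = None
    path: object | None = None
    path_string: str | None = None
    rmsd: object = None
    rmsf: object = None
    torsions: dict = field(default_factory=dict)
    report: pd.DataFrame | None = None


class StageError(HydronetError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except HydronetError as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_full_analysis(
    config: AnalysisConfig,
    ensemble: Ensemble | None = None,
    write_outputs: bool = True,
) -> AnalysisResult:
    """Align -> detect -> cluster waters -> occupancy -> graph -> path ->
    reports, deterministically for a given input and seed.

    ``ensemble`` may be passed directly (e.g. a freshly simulated one);
    otherwise ``config.input_path`` is read.  With ``write_outputs`` the
    CSV/JSON bundle lands in ``config.output_dir``.
    """
    cfg = config
    if ensemble is None:
        if cfg.input_path is None:
            raise ValueError("no ensemble given and config.input_path unset")
        ensemble = read_structure(
            cfg.input_path,
            water_resnames=cfg.water_resnames,
            frame_interval=cfg.frame_interval_ps,
        )
    water_resnames = frozenset(cfg.water_resnames)

    aligned, fit_rmsd = _stage("align")(align_ensemble)(ensemble, cfg.fit_selection)
    log.info("align: %d frames, mean fit RMSD %.3f A", aligned.n_frames, fit_rmsd.mean())

    events = _stage("detect")(detect_all_frames)(
        aligned, detect_hbonds, d_max=cfg.hbond_d_max
    )
    events += _stage("detect")(detect_all_frames)(
        aligned, detect_salt_bridges, d_max=cfg.salt_bridge_d_max
    )
    try:
        events += _stage("detect")(detect_all_frames)(
            aligned,
            detect_metal_coordination,
            metal_selection=cfg.metal_selection,
            d_max=cfg.metal_d_max,
        )
    except ValueError:
        log.info("detect: no metal atoms match %r; metal stage skipped", cfg.metal_selection)
    log.info("detect: %d events", len(events))

    params = ClusterParams(
        link_cutoff=cfg.link_cutoff,
        min_occupancy_report=cfg.min_occupancy_report,
        conserved_threshold=cfg.conserved_threshold,
        semi_threshold=cfg.semi_threshold,
    )
    sites = _stage("waters")(cluster_water_sites)(
        aligned, params, water_resnames=water_resnames
    )
    log.info("waters: %d sites", len(sites))

    occ = occupancy(events, key_fn=residue_pair_key, n_frames=aligned.n_frames)

    g = _stage("graph")(graphmod.build_graph)(
        aligned,
        events,
        sites,
        occ_min=cfg.occ_min,
        ligand_resnames=cfg.ligand_resnames or None,
        charged_atoms=cfg.charged_atoms,
        water_resnames=water_resnames,
    )
    path = path_string = None
    if cfg.path_source and cfg.path_targets:
        path = _stage("path")(graphmod.find_path)(g, cfg.path_source, cfg.path_targets)
        path_string = graphmod.format_path(path, g) if path else None
        log.info("path: %s", path_string or "no path found")
    else:
        log.info("path: no source/targets configured; stage skipped")

    rmsd = rmsd_series(aligned, cfg.fit_selection)
    rmsf = rmsf_per_residue(aligned, cfg.fit_selection)

    torsions = {}
    for t in cfg.torsions:
        spec = TorsionSpec(t["label"], [tuple(a) for a in t["atoms"]])
        torsions[t["label"]] = [
            measure_torsion(frame, spec) for frame in aligned.frames
        ]

    report = None
    if cfg.tracked:
        tracked = [
            TrackedInteraction(
                label=t["label"],
                atom_a=tuple(t["atom_a"]),
                atom_b=tuple(t["atom_b"]) if "atom_b" in t else None,
                site_id=t.get("site"),
            )
            for t in cfg.tracked
        ]
        rspec = ReportSpec(
            tracked=tracked,
            snapshot_times_ps=cfg.snapshot_times_ps,
            d_max=cfg.hbond_d_max,
        )
        report = tracked_report(aligned, events, sites, rspec)

    result = AnalysisResult(
        aligned=aligned,
        fit_rmsd=fit_rmsd,
        events=events,
        occupancy_records=occ,
        sites=sites,
        graph=g,
        path=path,
        path_string=path_string,
        rmsd=rmsd,
        rmsf=rmsf,
        torsions=torsions,
        report=report,
    )
    if write_outputs:
        _write_bundle(result, cfg)
    return result


def _write_bundle(result: AnalysisResult, cfg: AnalysisConfig) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash
    _write_csv(result.rmsd.to_dataframe(), out / "rmsd.csv", h)
    _write_csv(result.rmsf.to_dataframe(), out / "rmsf.csv", h)
    _write_csv(
        events_to_dataframe(result.events, cfg.frame_interval_ps),
        out / "events.csv",
        h,
    )
    occ_df = pd.DataFrame(
        [
            {
                "key": repr(r.key),
                "n_present": r.n_present,
                "n_total": r.n_total,
                "of_percent": r.of_percent,
            }
            for r in result.occupancy_records
        ]
    )
    _write_csv(occ_df, out / "occupancy.csv", h)
    _write_csv(sites_to_dataframe(result.sites), out / "sites.csv", h)
    if result.graph is not None:
        _write_csv(graphmod.graph_to_edge_table(result.graph), out / "graph_edges.csv", h)
    path_payload = {
        "config_hash": h,
        "path": None
        if result.path is None
        else {
            "nodes": result.path.nodes,
            "edge_kinds": result.path.edge_kinds,
            "hops": result.path.hops,
            "min_occupancy": result.path.min_occupancy,
            "water_site_count": result.path.water_site_count,
            "formatted": result.path_string,
        },
    }
    (out / "path.json").write_text(json.dumps(path_payload, indent=2))
    if result.report is not None:
        _write_csv(result.report, out / "report.csv", h)
    cfg.to_yaml(out / "config.yaml")
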