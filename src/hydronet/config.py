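"""Analysis configuration: every numeric convention in one auditable place.

The defaults are the package's standing conventions: 3.5 A heavy-atom
hydrogen bonds, 4.0 A salt bridges, 3.0 A metal coordination, 4.0-7.0 A /
60-120 deg T-stacking, 1.8 A water-site pairing, 90/60 % conservation
thresholds, 50 % minimum edge occupancy, 2 ps frames.  A config round-trips
losslessly through YAML, and its hash is embedded in every output file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # inputs / outputs
    input_path: str | None = None
    output_dir: str = "hydronet_out"
    seed: int = 0

    # selections
    fit_selection: str = "protein and backbone"
    water_resnames: list = field(default_factory=lambda: ["HOH", "WAT", "TIP3", "SOL"])
    ligand_resnames: list = field(default_factory=list)
    metal_selection: str = "element CU"

    # cutoffs (A / degrees / percent)
    hbond_d_max: float = 3.5
    salt_bridge_d_max: float = 4.0
    metal_d_max: float = 3.0
    pi_d_window: list = field(default_factory=lambda: [4.0, 7.0])
    pi_angle_window: list = field(default_factory=lambda: [60.0, 120.0])
    link_cutoff: float = 1.8
    min_occupancy_report: float = 10.0
    conserved_threshold: float = 90.0
    semi_threshold: float = 60.0
    occ_min: float = 50.0

    # trajectory conventions
    frame_interval_ps: float = 2.0
    snapshot_times_ps: list = field(default_factory=list)

    # ligand torsions: list of {label, atoms: [[res_seq, name] x4]}
    torsions: list = field(default_factory=list)
    # tracked interactions: list of {label, atom_a: [res_seq, name],
    #                                atom_b: [res_seq, name] | site: "WS1"}
    tracked: list = field(default_factory=list)

    # recognition path endpoints (graph node ids)
    path_source: str | None = None
    path_targets: list = field(default_factory=list)
    charged_atoms: list = field(default_factory=lambda: ["N1"])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
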