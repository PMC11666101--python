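"""Pinned run configuration with provenance tags.

Every tunable parameter of the pipeline lives here with its value and a
provenance tag: ``source`` means the value restates a protocol constant
of the study design (snapshot protocol 150/5, pulling velocity/force
analogs, membrane composition); ``default`` means it is an artifact
decision of this package (cutoffs, verdict thresholds, sampler
temperature).  Configurations are layered (packaged defaults < user
file < explicit overrides), reject unknown keys, and are echoed into
every output bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

DEFAULTS: dict[str, tuple[object, str]] = {
    # seq_sites
    "gap_open": (-10.0, "default"),
    "gap_extend": (-0.5, "default"),
    # graft_sample
    "snapshots": (30, "source"),  # 150 ns horizon / 5 ns interval analog
    "interval": (5, "source"),
    "move_width_deg": (30.0, "default"),
    "temperature": (0.05, "default"),
    "clash_cutoff_A": (2.4, "default"),
    "max_attempts": (500, "default"),
    "head_tolerance_A": (3.0, "default"),
    # occupancy_occlusion
    "contact_cutoff_A": (4.5, "default"),
    "interface_cutoff_A": (5.0, "default"),
    "voxel_size_A": (1.0, "default"),
    "frame_fraction": (0.5, "default"),
    "blocked_threshold": (0.8, "default"),
    "accessible_threshold": (0.2, "default"),
    "pore_radius_A": (6.0, "default"),
    "pore_length_A": (30.0, "default"),
    # trans_bridge
    "contour_per_residue_A": (3.63, "default"),
    "pull_velocity": (5.0, "source"),  # 5 nm/ns analog
    "pull_spring_k": (100.0, "source"),  # 100 kJ/mol nm^2 analog
    "interface_k": (10.0, "default"),
    "break_extension_A": (1.0, "default"),
    "pull_dt": (0.0005, "default"),
    "pull_max_steps": (60000, "default"),
    "report_offset": (10, "source"),  # "shortly before rupture" analog
    # global
    "seed": (0, "default"),
}


@dataclass
class RunConfig:
    """Layered, provenance-tagged parameter set."""

    values: dict[str, object] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        merged = {k: v for k, (v, _) in DEFAULTS.items()}
        prov = {k: p for k, (_, p) in DEFAULTS.items()}
        for k, v in self.values.items():
            if k not in DEFAULTS:
                raise KeyError(f"unknown config key {k!r}")
            merged[k] = v
            prov[k] = "user"
        self.values = merged
        self.provenance = prov

    def __getitem__(self, key: str):
        return self.values[key]

    def override(self, **kwargs) -> "RunConfig":
        base = {k: v for k, v in self.values.items() if self.provenance[k] == "user"}
        base.update(kwargs)
        return RunConfig(values=base)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls(values=json.loads(Path(path).read_text()))

    def echo(self) -> dict:
        """Serializable copy embedded into every output artifact."""
        return {
            k: {"value": self.values[k], "provenance": self.provenance[k]}
            for k in sorted(self.values)
        }
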