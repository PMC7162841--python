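"""Analysis configuration: every geometric threshold in one place.

The underlying dichotomies (parallel vs inverted topology, helix contact,
acceptable protodomain match) are stated qualitatively in the literature; the
numeric cutoffs realizing them are package choices and are all exposed here
and overridable from a flat YAML file or CLI flags.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


class ConfigError(Exception):
    pass


@dataclass
class AnalysisConfig:
    # protodomain structural alignment
    d_cut: float = 6.0                 # Å; DP match window
    trim_cut: float = 5.0              # Å; residual cutoff for final pairs
    max_iter: int = 10                 # DP refinement rounds
    converge: float = 0.01             # Å; RMSD change declaring convergence
    internal_gap_penalty: float = 3.0  # per-residue cost of within-helix gaps
    min_final_pairs: int = 9
    # symmetry detection
    angle_tol: float = 15.0            # deg; rotation angle vs 360/order
    perp_tol: float = 20.0             # deg; axis parallel/perpendicular test
    rmsd_accept: float = 4.0           # Å; max RMSD for a symmetry candidate
    parallel_max_axis_angle: float = 45.0  # deg; axis-normal angle splitting
    #                                    parallel from inverted topology
    identity_threshold: float = 0.9    # chain equivalence for quaternary sets
    # topology codes
    contact_cut: float = 12.0          # Å; projected centroid contact distance
    min_triangle_area: float = 1.0     # Å^2; chirality defined above this
    # TM segment assignment / hydropathy prediction
    min_segment_length: int = 12
    helical_fraction: float = 0.7
    helix_d13_range: tuple[float, float] = (4.5, 5.7)  # Å; Cα i->i+3
    span_fraction: float = 0.8         # of the core width a segment must cover
    window: int = 19                   # hydropathy moving-average window
    hydropathy_threshold: float = 1.6  # Kyte-Doolittle scale units
    core_half_width: float = 15.0      # Å; membrane core half-width

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        if not isinstance(data, dict):
            raise ConfigError("config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "helix_d13_range" in data:
            data = dict(data)
            data["helix_d13_range"] = tuple(data["helix_d13_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("d_cut", "trim_cut", "angle_tol", "perp_tol", "rmsd_accept",
                     "contact_cut", "core_half_width"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.window % 2 == 0 or self.window < 3:
            raise ConfigError("window must be an odd integer >= 3")
        if not 0 < self.identity_threshold <= 1:
            raise ConfigError("identity_threshold must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["helix_d13_range"] = list(d["helix_d13_range"])
        return d
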