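"""Structured run configuration with strict key validation and seed fan-out."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class WhiskerConfig:
    arc_length_mm: float = 20.0
    taper_ratio: float = 15.0
    base_radius_um: float = 100.0
    quad_coeff: float = 0.02
    oop_cubic_coeff: float = 0.12
    n_nodes: int = 100
    youngs_modulus_gpa: float = 3.0
    poisson_ratio: float = 0.38
    points_file: str | None = None  # overrides the synthetic shape


@dataclass
class GridConfig:
    r_min_mm: float = 6.0
    r_max_mm: float = 20.0
    r_step_mm: float = 2.0
    theta_min_deg: float = -65.0
    theta_max_deg: float = 65.0
    theta_step_deg: float = 3.0
    phi_min_deg: float = -60.0
    phi_max_deg: float = 60.0
    phi_step_deg: float = 3.0
    cone_deg: float = 2.0


@dataclass
class UniquenessConfig:
    run: bool = True
    region: str = "All"
    median_r_mm: float = 1.0
    median_angle_deg: float = 2.0
    eps_sig: float = 0.2
    eps_cp_mm: float = 5.0
    n_seeds: int = 3
    min_records: int = 1000


@dataclass
class SensitivityConfig:
    run: bool = True
    full_table_envelope: bool = False  # default: behavioral-trial envelope
    n_bins: int = 50
    trim: float = 0.99


@dataclass
class WhiskConfig:
    run: bool = True
    amplitude_deg: float = 25.0
    frequency_hz: float = 6.0
    n_cycles: int = 3
    elevation_amp_deg: float = 6.0
    basepoint_jitter_mm: float = 0.06
    angle_jitter_deg: float = 0.5
    slip_max_deg: float = 12.0
    cutoff_hz: float = 85.0
    peg_x_mm: float = 9.97
    peg_y_mm: float = 4.65
    peg_diameter_mm: float = 2.7
    triplet: str = "Fx,MB,MD"


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "whiskmap-run"
    whisker: WhiskerConfig = field(default_factory=WhiskerConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    uniqueness: UniquenessConfig = field(default_factory=UniquenessConfig)
    sensitivity: SensitivityConfig = field(default_factory=SensitivityConfig)
    whisk: WhiskConfig = field(default_factory=WhiskConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @staticmethod
    def from_dict(payload: dict) -> "RunConfig":
        return _build(RunConfig, payload, "")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.from_dict(payload)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31 derived from the global one."""
        h = hashlib.blake2s(f"{self.seed}:{stage}".encode(), digest_size=4)
        return int.from_bytes(h.digest(), "big") % (2 ** 31)


def _build(cls, payload, prefix: str):
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in known:
            raise ParameterError(f"unknown config key {prefix}{key!r}")
        f = known[key]
        sub = {"whisker": WhiskerConfig, "grid": GridConfig,
               "uniqueness": UniquenessConfig, "sensitivity": SensitivityConfig,
               "whisk": WhiskConfig}.get(key)
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build(sub, value, f"{key}.")
        else:
            kwargs[key] = value
    return cls(**kwargs)
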