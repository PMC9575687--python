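"""Run configuration: one flat document holding every pipeline parameter.

Round-trips losslessly through YAML; unknown keys are rejected; a content
hash stamps derived artifacts for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from . import __version__


@dataclass
class RunConfig:
    # synthesis
    seed: int = 0
    preset: str = "two_arm_v"
    atoms_per_domain: int = 12
    n: int = 2
    M: int = 20
    tau: int = 10
    snr: float = 0.1
    datatype: str = "II"
    n_pds: int = 8
    P: int = 64
    blob_sigma: float = 1.5
    pixel_size_A: float = 1.0
    voltage_kV: float = 300.0
    spherical_aberration_mm: float = 2.7
    amplitude_contrast: float = 0.1
    defocus_min_um: float = 0.5
    defocus_max_um: float = 2.5
    occupancy_weights: list | None = None
    # embedding
    method: str = "DM"
    d: int = 15
    lowpass_sigma: float = 1.5
    kernel_occupancy: float = 0.3
    # realignment
    n_max: int = 2
    r2_detect: float = 0.2
    r2_min: float = 0.7
    operator_mode: str = "all_cross"
    theta_step_deg: float = 1.0
    hist_bins: int = 40
    conic_constraint: str = "auto"   # parabola (I/II), general (III/IV), or auto
    # partitioning
    B: int = 0                       # 0 = use M in synthetic mode, 50 otherwise
    arccos_quantile: float = 0.05
    halve: bool = False
    # compilation
    sense_mode: str = "ground_truth"
    kT: float = 1.0

    def __post_init__(self):
        if self.datatype not in ("I", "II", "III", "IV"):
            raise ValueError(f"unknown datatype {self.datatype!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    @property
    def provenance(self) -> str:
        return f"esper {__version__} config {self.config_hash}"

    def microscope(self):
        from .synthetic import MicroscopeParams
        return MicroscopeParams(
            voltage_kV=self.voltage_kV,
            spherical_aberration_mm=self.spherical_aberration_mm,
            amplitude_contrast=self.amplitude_contrast,
            pixel_size_A=self.pixel_size_A,
            defocus_range_um=(self.defocus_min_um, self.defocus_max_um),
        )

    @property
    def constraint(self) -> str:
        if self.conic_constraint != "auto":
            return self.conic_constraint
        return "general" if self.datatype in ("III", "IV") else "parabola"
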