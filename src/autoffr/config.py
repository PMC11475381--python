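"""TOML configuration for the end-to-end pipeline.

One config object gathers every tunable of the workflow with the package
defaults; a TOML file overrides individual keys section by section
([filters], [aorta], [clustering], [cleaning], [geometry], [blood],
[wall], [windkessel], [inflow], [solver]).  Re-running with tweaked
thresholds is a config edit, not code.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from .clustering import ClusterParams
from .constitutive import MMHG, BloodProperties, WallLaw
from .filtering import FilterParams
from .solver import SolverConfig
from .windkessel import DEFAULT_C1_FRACTION, DEFAULT_TOTAL_COMPLIANCE, MURRAY_POWER, PerfusionTargets


@dataclass
class AortaConfig:
    slice_start: int = 4  # fifth slice (1-based) of the cropped stack
    slice_stop: int = 9
    r_min: int = 25
    r_max: int = 60
    canny_low: float = 50.0
    canny_high: float = 150.0


@dataclass
class CleaningConfig:
    root_eps: float = 7.0
    root_min_pts: int = 700
    vessel_eps: float = 1.5
    vessel_min_pts: int = 3
    regularize: bool = True
    spur_min_length_mm: float = 3.0


@dataclass
class GeometryConfig:
    mesh_spacing_cm: float = 0.01
    trim_nodes: int = 5
    radius_method: str = "ring-median"


@dataclass
class WindkesselConfig:
    murray_power: float = MURRAY_POWER
    total_compliance: float = DEFAULT_TOTAL_COMPLIANCE
    c1_fraction: float = DEFAULT_C1_FRACTION
    pven_mmhg: float = 5.0
    plv_scale_left: float = 0.5
    plv_scale_right: float = 0.2


@dataclass
class InflowConfig:
    period_s: float = 0.8
    q_mean_left: float = 2.0
    q_mean_right: float = 1.0
    table_left: str | None = None  # CSV with t,Q columns; overrides the default shape
    table_right: str | None = None


@dataclass
class PipelineConfig:
    crop: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] = (
        (0.0, 1.0),
        (0.2, 0.8),
        (0.2, 0.8),
    )
    window_center: float | None = None
    window_width: float | None = None
    seed: int = 0
    filters: FilterParams = field(default_factory=FilterParams)
    aorta: AortaConfig = field(default_factory=AortaConfig)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    blood: BloodProperties = field(default_factory=BloodProperties)
    wall: WallLaw = field(default_factory=WallLaw)
    perfusion: PerfusionTargets = field(default_factory=PerfusionTargets)
    windkessel: WindkesselConfig = field(default_factory=WindkesselConfig)
    inflow: InflowConfig = field(default_factory=InflowConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)

    _SECTIONS = {
        "filters": "filters",
        "aorta": "aorta",
        "clustering": "clustering",
        "cleaning": "cleaning",
        "geometry": "geometry",
        "blood": "blood",
        "wall": "wall",
        "perfusion": "perfusion",
        "windkessel": "windkessel",
        "inflow": "inflow",
        "solver": "solver",
    }

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cfg = cls()
        for key in ("seed", "window_center", "window_width"):
            if key in data:
                setattr(cfg, key, data[key])
        if "crop" in data:
            cfg.crop = tuple(tuple(pair) for pair in data["crop"])
        for section, attr in cls._SECTIONS.items():
            if section not in data:
                continue
            obj = getattr(cfg, attr)
            valid = {f.name for f in dataclasses.fields(obj)}
            for k, v in data[section].items():
                if k not in valid:
                    raise KeyError(f"unknown key '{k}' in config section [{section}]")
                if isinstance(v, list):
                    v = tuple(v)
                setattr(obj, k, v)
            if hasattr(obj, "__post_init__"):
                obj.__post_init__()
        return cfg

    def snapshot(self) -> dict:
        """JSON-serialisable echo of every parameter (for the run manifest)."""

        def conv(o):
            if dataclasses.is_dataclass(o):
                return {f.name: conv(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, tuple):
                return list(o)
            return o

        return conv(self)
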