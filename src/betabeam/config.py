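"""Experiment configuration: YAML round-trip, hashing, geometry assembly.

A single :class:`ExperimentConfig` describes everything a run needs —
helmet and head geometry, trial paradigm, noise condition, beamformer
settings, the resolution-study schedule and the volumetric-map grid — plus
one master seed.  Every output file produced by the command-line layer
embeds the config hash and seed so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .geometry import (
    EllipsoidSurface,
    HeadModel,
    SensorArray,
    fit_local_spheres,
    make_helmet_array,
    shrink_surface,
)
from .resolution import ResolutionCriterion, StudyConfig
from .simulate import NoiseModel, Paradigm

__all__ = [
    "GeometryConfig",
    "ParadigmConfig",
    "NoiseConfig",
    "BeamformerConfig",
    "StudySection",
    "MapSection",
    "SimulateSection",
    "ExperimentConfig",
    "Geometry",
    "build_geometry",
]


@dataclass(frozen=True)
class GeometryConfig:
    n_channels: int = 275
    helmet_radius_m: float = 0.12
    coverage: float = 0.5
    helmet_seed: int = 0
    semi_axes_m: tuple[float, float, float] = (0.09, 0.07, 0.065)
    center_m: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shrink_depth_m: float = 0.015
    head_mode: str = "local_spheres"
    patch_radius_m: float = 0.04


@dataclass(frozen=True)
class ParadigmConfig:
    trial_length_s: float = 20.0
    sampling_rate_hz: float = 600.0
    n_trials: int = 44
    active_windows: tuple[tuple[int, float, float], ...] = ((0, 0.0, 2.0), (1, 10.0, 12.0))


@dataclass(frozen=True)
class NoiseConfig:
    kind: str = "gaussian"
    amplitude_ft: float = 21.0


@dataclass(frozen=True)
class BeamformerConfig:
    methods: tuple[int, ...] = (1, 2, 3)
    regularisation: float = 0.0
    band_hz: tuple[float, float] | None = None


@dataclass(frozen=True)
class StudySection:
    n_repeats: int = 50
    d_start_mm: float = 30.0
    d_step_mm: float = 0.5
    dip_ratio: float = 0.8
    search: str = "bisect"
    margin_mm: float = 10.0
    profile_step_mm: float = 0.5
    snr_condition: str = "medium"
    retry_cap: int = 8


@dataclass(frozen=True)
class MapSection:
    grid_spacing_mm: float = 2.0
    grid_half_extent_mm: float = 12.0
    band_hz: tuple[float, float] = (13.0, 30.0)


@dataclass(frozen=True)
class SimulateSection:
    separation_mm: float = 12.0
    amplitude_mean_nam: float = 31.0
    amplitude_sd_nam: float = 3.0


@dataclass(frozen=True)
class ExperimentConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    beamformer: BeamformerConfig = field(default_factory=BeamformerConfig)
    study: StudySection = field(default_factory=StudySection)
    map: MapSection = field(default_factory=MapSection)
    simulate: SimulateSection = field(default_factory=SimulateSection)
    seed: int = 0

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        def sub(klass, key):
            block = d.get(key, {}) or {}
            try:
                return klass(**_tuplify(block))
            except TypeError as exc:
                raise ValueError(f"invalid config field in block '{key}': {exc}") from exc

        return cls(
            geometry=sub(GeometryConfig, "geometry"),
            paradigm=sub(ParadigmConfig, "paradigm"),
            noise=sub(NoiseConfig, "noise"),
            beamformer=sub(BeamformerConfig, "beamformer"),
            study=sub(StudySection, "study"),
            map=sub(MapSection, "map"),
            simulate=sub(SimulateSection, "simulate"),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text) or {}
        if not isinstance(d, dict):
            raise ValueError("config YAML must be a mapping")
        return cls.from_dict(d)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    # -- derived runtime objects -------------------------------------------

    def make_paradigm(self) -> Paradigm:
        p = self.paradigm
        return Paradigm(
            trial_length=p.trial_length_s,
            sampling_rate=p.sampling_rate_hz,
            n_trials=p.n_trials,
            active_windows=tuple(tuple(w) for w in p.active_windows),
        )

    def make_noise(self) -> NoiseModel:
        return NoiseModel(kind=self.noise.kind, gaussian_amplitude=self.noise.amplitude_ft)

    def make_study_config(self) -> StudyConfig:
        s = self.study
        return StudyConfig(
            n_repeats=s.n_repeats,
            d_start=s.d_start_mm * 1e-3,
            d_step=s.d_step_mm * 1e-3,
            snr_condition=s.snr_condition,
            methods=tuple(self.beamformer.methods),
            seed=self.seed,
            search=s.search,
            margin=s.margin_mm * 1e-3,
            profile_step=s.profile_step_mm * 1e-3,
            criterion=ResolutionCriterion(dip_ratio=s.dip_ratio),
            paradigm=self.make_paradigm(),
            amplitude_mean=self.simulate.amplitude_mean_nam,
            amplitude_sd=self.simulate.amplitude_sd_nam,
            retry_cap=s.retry_cap,
        )


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def _tuplify(block: dict) -> dict:
    out = {}
    for k, v in block.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out


@dataclass(frozen=True)
class Geometry:
    """The assembled measurement setup of one experiment."""

    sensors: SensorArray
    head_surface: EllipsoidSurface
    source_surface: EllipsoidSurface
    head_model: HeadModel


def build_geometry(config: GeometryConfig | ExperimentConfig = GeometryConfig()) -> Geometry:
    """Helmet, head/source ellipsoids and conductor model from a config block."""
    gc = config.geometry if isinstance(config, ExperimentConfig) else config
    sensors = make_helmet_array(
        n_channels=gc.n_channels,
        radius=gc.helmet_radius_m,
        coverage=gc.coverage,
        seed=gc.helmet_seed,
    )
    head_surface = EllipsoidSurface(
        center=np.asarray(gc.center_m), semi_axes=np.asarray(gc.semi_axes_m)
    )
    source_surface = shrink_surface(head_surface, gc.shrink_depth_m)
    head_model = fit_local_spheres(
        head_surface, sensors, patch_radius=gc.patch_radius_m, mode=gc.head_mode
    )
    return Geometry(
        sensors=sensors,
        head_surface=head_surface,
        source_surface=source_surface,
        head_model=head_model,
    )
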