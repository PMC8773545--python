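"""Structured run configuration with full defaults and strict key checking.

A single YAML file (all keys optional — an empty file is the default run)
configures every pipeline stage.  Unknown keys anywhere raise
:class:`ConfigurationError` naming the offending key, so typos cannot
silently fall back to defaults.

Top-level sections::

    seed:        global integer seed
    simulation:  stack, geometry, noise, ri_levels, frames_per_level,
                 frame_shape, stability, binding
    training:    hidden_dim, n_train, learning_rate, max_epochs,
                 tolerance, momentum, restarts
    metrics:     ri_per_pm (RIU per pM of analyte)

Units: layer thicknesses nm, core diameter µm, sensing length mm, times s.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .imaging import DEFAULT_RI_LEVELS, BindingKinetics, NoiseModel, SpotProfile, default_profiles
from .metrics import RI_PER_PM_IGG
from .network import SplitSpec, TrainConfig
from .optics import LayerStack, SensorGeometry

__all__ = ["RunConfig", "load_config"]


def _take(section: dict, name: str, allowed: set[str]) -> dict:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in config section {name!r}")
    return section


@dataclass(frozen=True)
class StabilityConfig:
    ri: float = 1.352
    n_frames: int = 60
    frame_interval: float = 10.0


@dataclass(frozen=True)
class BindingConfig:
    baseline_ri: float = 1.350
    delta_ri_max: float = 9.0e-4
    k_obs: float = 0.01
    injection_time: float = 100.0
    frame_interval: float = 10.0
    duration: float = 700.0

    def kinetics(self) -> BindingKinetics:
        return BindingKinetics(self.delta_ri_max, self.k_obs, self.injection_time, self.frame_interval)


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated configuration of a pipeline run."""

    seed: int = 0
    stack: LayerStack = field(default_factory=LayerStack)
    geometry: SensorGeometry = field(default_factory=SensorGeometry)
    noise: NoiseModel = field(default_factory=NoiseModel)
    ri_levels: tuple[float, ...] = DEFAULT_RI_LEVELS
    frames_per_level: int = 10
    frame_shape: tuple[int, int] = (480, 640)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    binding: BindingConfig = field(default_factory=BindingConfig)
    hidden_dim: int = 10
    n_train: int = 45
    train: TrainConfig = field(default_factory=TrainConfig)
    ri_per_pm: float = RI_PER_PM_IGG

    def profiles(self) -> dict[str, SpotProfile]:
        return default_profiles(self.frame_shape)

    def split(self) -> SplitSpec:
        n_total = len(self.ri_levels) * self.frames_per_level
        return SplitSpec(n_total=n_total, n_train=self.n_train, seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulation": {
                "stack": {
                    "substrate_index": self.stack.substrate_index,
                    "layers": [list(layer) for layer in self.stack.layers],
                    "analyte_index": self.stack.analyte_index,
                },
                "geometry": {
                    "core_diameter": self.geometry.core_diameter,
                    "sensing_length": self.geometry.sensing_length,
                    "numerical_aperture": self.geometry.numerical_aperture,
                    "angle_grid": list(self.geometry.angle_grid),
                },
                "noise": asdict(self.noise),
                "ri_levels": list(self.ri_levels),
                "frames_per_level": self.frames_per_level,
                "frame_shape": list(self.frame_shape),
                "stability": asdict(self.stability),
                "binding": asdict(self.binding),
            },
            "training": {
                "hidden_dim": self.hidden_dim,
                "n_train": self.n_train,
                **asdict(self.train),
            },
            "metrics": {"ri_per_pm": self.ri_per_pm},
        }

    def sha256(self) -> str:
        """Hash of the canonical YAML dump, recorded in run metadata."""
        dump = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(dump.encode()).hexdigest()

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = _take(dict(raw or {}), "<root>", {"seed", "simulation", "training", "metrics"})
        sim = _take(
            dict(raw.get("simulation") or {}),
            "simulation",
            {"stack", "geometry", "noise", "ri_levels", "frames_per_level", "frame_shape", "stability", "binding"},
        )
        tr = _take(
            dict(raw.get("training") or {}),
            "training",
            {"hidden_dim", "n_train", "learning_rate", "max_epochs", "tolerance", "momentum", "restarts", "seed"},
        )
        met = _take(dict(raw.get("metrics") or {}), "metrics", {"ri_per_pm"})

        stack_kw = _take(dict(sim.get("stack") or {}), "stack", {"substrate_index", "layers", "analyte_index"})
        if "layers" in stack_kw:
            stack_kw["layers"] = tuple((m, float(d)) for m, d in stack_kw["layers"])
        geom_kw = _take(
            dict(sim.get("geometry") or {}),
            "geometry",
            {"core_diameter", "sensing_length", "numerical_aperture", "angle_grid"},
        )
        if "angle_grid" in geom_kw:
            geom_kw["angle_grid"] = tuple(geom_kw["angle_grid"])
        noise_kw = _take(
            dict(sim.get("noise") or {}),
            "noise",
            {"fluctuation_sigma", "fluctuation_rho", "shot_scale", "read_sigma", "seed"},
        )
        stab_kw = _take(dict(sim.get("stability") or {}), "stability", {"ri", "n_frames", "frame_interval"})
        bind_kw = _take(
            dict(sim.get("binding") or {}),
            "binding",
            {"baseline_ri", "delta_ri_max", "k_obs", "injection_time", "frame_interval", "duration"},
        )
        train_kw = {k: tr[k] for k in ("learning_rate", "max_epochs", "tolerance", "momentum", "restarts", "seed") if k in tr}
        return cls(
            seed=int(raw.get("seed", 0)),
            stack=LayerStack(**stack_kw),
            geometry=SensorGeometry(**geom_kw),
            noise=NoiseModel(**noise_kw),
            ri_levels=tuple(sim.get("ri_levels", DEFAULT_RI_LEVELS)),
            frames_per_level=int(sim.get("frames_per_level", 10)),
            frame_shape=tuple(sim.get("frame_shape", (480, 640))),
            stability=StabilityConfig(**stab_kw),
            binding=BindingConfig(**bind_kw),
            hidden_dim=int(tr.get("hidden_dim", 10)),
            n_train=int(tr.get("n_train", 45)),
            train=TrainConfig(**train_kw),
            ri_per_pm=float(met.get("ri_per_pm", RI_PER_PM_IGG)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path=None) -> RunConfig:
    """Load a YAML config; a missing argument or empty file means defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.from_dict(raw or {})
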