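"""Run configuration, serialization and seeded fixture generation.

One YAML dialect throughout: a run is reproducible from its config plus the
code version.  Unknown keys are rejected with a schema error naming them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .meanfield import Grid, ModelParams

__all__ = [
    "ConfigError",
    "NumericsConfig",
    "ProtocolConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "write_manifest",
    "seed_streams",
    "generate_fixtures",
]


class ConfigError(ValueError):
    """Schema violation; message lists the offending keys/fields."""


def seed_streams(seed: int, *names: str) -> dict:
    """Split one top-level seed into named, order-independent child streams."""
    root = np.random.SeedSequence(seed)
    return {name: np.random.default_rng(
        np.random.SeedSequence(entropy=root.entropy,
                               spawn_key=(hash(name) % (2 ** 32),)))
        for name in names}


@dataclass
class NumericsConfig:
    n_theta: int = 256
    n_phi: int = 129
    rtol: float = 1e-6
    atol: float = 1e-8
    dt_noise_fraction: float = 0.01  # EM step as a fraction of tau

    def grid(self) -> Grid:
        return Grid(n_theta=self.n_theta, n_phi=self.n_phi)


@dataclass
class ProtocolConfig:
    kind: str = "none"      # none | static | moving | two_stimulus | slow_morph
    map_select: str = "A"
    location: float = 0.0
    velocity: float = 0.0
    eps: float = 0.0
    durations: list = field(default_factory=list)
    morph_duration: float = 0.0
    n_trials: int = 0


@dataclass
class RunConfig:
    model: ModelParams
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    seed: int = 0
    t_end: float = 100.0
    n_neurons: int = 1000
    out_dir: Optional[str] = None


def _from_mapping(cls, data: dict, where: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {where!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ConfigError(f"unknown keys in {where!r}: {', '.join(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid {where!r} section: {err}") from err


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - top)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {', '.join(unknown)}")
    if "model" not in raw:
        raise ConfigError("config must contain a 'model' section")
    model = _from_mapping(ModelParams, raw["model"], "model")
    protocol = _from_mapping(ProtocolConfig, raw.get("protocol", {}), "protocol")
    numerics = _from_mapping(NumericsConfig, raw.get("numerics", {}), "numerics")
    scalars = {k: raw[k] for k in ("seed", "t_end", "n_neurons", "out_dir")
               if k in raw}
    return RunConfig(model=model, protocol=protocol, numerics=numerics,
                     **scalars)


def save_config(config: RunConfig, path) -> None:
    data = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir, extra: Optional[dict] = None) -> Path:
    """Write the reproducibility manifest next to a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "code_version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def write_results(outputs: dict, out_dir, config: Optional[RunConfig] = None,
                  extra: Optional[dict] = None) -> list:
    """Write run outputs (DataFrames -> CSV, mappings -> JSON) plus the
    manifest; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in outputs.items():
        if hasattr(obj, "to_csv"):
            path = out_dir / f"{name}.csv"
            obj.to_csv(path, index=False)
        else:
            path = out_dir / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, default=float))
        written.append(path)
    if config is not None:
        written.append(write_manifest(config, out_dir, extra))
    return written


def generate_fixtures(seed: int = 0) -> dict:
    """Small seeded configs covering every regime at desk scale.

    The parameter points are chosen from the analytic boundaries: see
    phase.classify_regime for the labels they produce.
    """
    fixtures = {
        "homogeneous": RunConfig(
            model=ModelParams(d=0.5, J_mod=0.8, J_inh=2.0), seed=seed),
        "single_ring": RunConfig(
            model=ModelParams(d=0.3, J_mod=3.0, J_inh=4.0), seed=seed + 1),
        "double_ring": RunConfig(
            model=ModelParams(d=1.0, J_mod=2.6, J_inh=4.0), seed=seed + 2),
        "cylinder": RunConfig(
            model=ModelParams(d=0.8, J_mod=10.0, J_inh=10.0), seed=seed + 3),
        "amplitude_unstable": RunConfig(
            model=ModelParams(d=0.3, J_mod=3.0, J_inh=0.05), seed=seed + 4),
    }
    for cfg in fixtures.values():
        cfg.numerics = NumericsConfig(n_theta=128, n_phi=65)
        cfg.n_neurons = 400
    return fixtures
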