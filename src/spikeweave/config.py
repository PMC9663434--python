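"""Validated run configuration: nested sections mirroring the model params.

A config file is a YAML document with optional sections; every omitted value
falls back to the built-in defaults (LIF constants 20/10 ms, threshold 18 mV,
refractory 2/1 ms, latency 1 ms, dt 0.05 ms, 80/20 E/I split at p = 0.2,
STDP amplitudes 0.06/0.05 with 0.4 interneuron scaling).  Unknown keys and
type mismatches are rejected with descriptive errors.  A single global seed
fans out deterministically to per-stage seeds via ``stage_seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import NeuronParams, SynapseParams
from .encoding import CodingParams
from .plasticity import PlasticityParams
from .training import TrainingSchedule

__all__ = ["TopologyConfig", "CoherenceConfig", "RunConfig", "load_config", "stage_seed"]


@dataclass(frozen=True)
class TopologyConfig:
    n: int = 5000
    frac_exc: float = 0.8
    grid: tuple[int, int] = (100, 50)
    p: float = 0.2
    j_ext: float = 5.0
    n_classes: int = 10

    def __post_init__(self) -> None:
        if self.n < 1 or not 0 < self.p <= 1:
            raise ValueError("need n >= 1 and p in (0, 1]")
        if self.n > self.grid[0] * self.grid[1]:
            raise ValueError("population exceeds grid capacity")


@dataclass(frozen=True)
class CoherenceConfig:
    threshold: float = 0.8
    shared_count: int = 500
    lfp_gain: float = 1.0
    ref_dt: float = 5.0
    transient_ms: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


_SECTIONS = {
    "neuron_exc": NeuronParams,
    "neuron_inh": NeuronParams,
    "synapse": SynapseParams,
    "coding": CodingParams,
    "plasticity": PlasticityParams,
    "schedule": TrainingSchedule,
    "topology": TopologyConfig,
    "coherence": CoherenceConfig,
}


@dataclass
class RunConfig:
    neuron_exc: NeuronParams = field(default_factory=NeuronParams.excitatory)
    neuron_inh: NeuronParams = field(default_factory=NeuronParams.inhibitory)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    coding: CodingParams = field(default_factory=CodingParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    coherence: CoherenceConfig = field(default_factory=CoherenceConfig)
    dt: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        out: dict = {"dt": self.dt, "seed": self.seed}
        for name in _SECTIONS:
            section = dataclasses.asdict(getattr(self, name))
            if "grid" in section:
                section["grid"] = list(section["grid"])
            out[name] = section
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ValueError("config document must be a mapping")
        unknown = set(doc) - set(_SECTIONS) - {"dt", "seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for name, klass in _SECTIONS.items():
            sub = doc.get(name, {})
            if not isinstance(sub, dict):
                raise ValueError(f"section {name!r} must be a mapping")
            valid = {f.name: f.type for f in dataclasses.fields(klass)}
            bad = set(sub) - set(valid)
            if bad:
                raise ValueError(f"unknown keys in {name!r}: {sorted(bad)}")
            coerced = {}
            for key, val in sub.items():
                if key == "grid":
                    val = tuple(int(v) for v in val)
                elif isinstance(val, bool) or not isinstance(
                    val, (int, float, str)
                ):
                    raise ValueError(
                        f"{name}.{key}: expected a scalar, got {type(val).__name__}"
                    )
                coerced[key] = val
            defaults = cls.__dataclass_fields__[name].default_factory()
            base = dataclasses.asdict(defaults)
            if "grid" in base:
                base["grid"] = defaults.grid
            base.update(coerced)
            try:
                kwargs[name] = klass(**base)
            except TypeError as exc:
                raise ValueError(f"section {name!r}: {exc}") from exc
        for key in ("dt", "seed"):
            if key in doc:
                if not isinstance(doc[key], (int, float)):
                    raise ValueError(f"{key} must be numeric")
                kwargs[key] = doc[key]
        cfg = cls(**kwargs)
        if cfg.dt <= 0:
            raise ValueError("dt must be positive")
        return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; missing values take the defaults."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file {p} does not exist")
    return RunConfig.from_dict(yaml.safe_load(p.read_text()))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
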