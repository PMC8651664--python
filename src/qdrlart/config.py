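"""Run configuration: nested YAML sections, validation and hashing.

A run config has sections ``cohort / arte / qdecision / agent /
augmentation / evaluation`` plus a global ``seed`` and ``outdir``.
Unknown keys are rejected so typos fail loudly, and every artifact the
pipeline writes embeds the config hash and seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .agent import TrainConfig
from .arte import EstimatorConfig, RadiobioParams
from .augmentation import GanConfig
from .cohort import CohortConfig
from .qdecision import DoseGrid

__all__ = ["RunConfig", "load_config", "default_config", "config_hash"]


@dataclass
class QDecisionConfig:
    n_qubits: int = 5
    d_min: float = 1.0
    d_max: float = 4.1
    backend: str = "controller-sim"   # controller-sim | grover-sim | external
    shots: int = 1024

    def grid(self) -> DoseGrid:
        return DoseGrid(self.n_qubits, self.d_min, self.d_max)


@dataclass
class ArteConfig:
    radbio: RadiobioParams = field(default_factory=RadiobioParams)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    transition_hidden: tuple[int, ...] = (32, 32)
    transition_epochs: int = 400
    max_steps: int = 10


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/default"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    arte: ArteConfig = field(default_factory=ArteConfig)
    qdecision: QDecisionConfig = field(default_factory=QDecisionConfig)
    agent: TrainConfig = field(default_factory=TrainConfig)
    augmentation: GanConfig = field(default_factory=GanConfig)


_SECTION_TYPES = {
    "cohort": CohortConfig,
    "arte": ArteConfig,
    "qdecision": QDecisionConfig,
    "agent": TrainConfig,
    "augmentation": GanConfig,
}
_NESTED = {"radbio": RadiobioParams, "estimator": EstimatorConfig}
_TUPLE_FIELDS = {"hidden", "critic_hidden", "gen_hidden", "transition_hidden"}


def _build(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) under '{path}': {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value, f"{path}.{key}")
        elif key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path_or_dict) -> RunConfig:
    """Load a RunConfig from a YAML file path or a nested dict."""
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    known = {"seed", "outdir", *(_SECTION_TYPES)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build(_SECTION_TYPES[key], value or {}, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def default_config(seed: int = 0, outdir: str = "runs/default") -> RunConfig:
    return RunConfig(seed=seed, outdir=outdir)


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the scientific configuration (the output
    directory does not affect results and is excluded)."""
    data = _jsonable(config)
    data.pop("outdir", None)
    blob = json.dumps(data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def config_to_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(_jsonable(config), sort_keys=True)
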