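"""YAML configuration with protocol defaults and strict validation.

An empty config resolves to the reference protocol defaults: 25 poses,
10 initialization replicates of 8 ps free + 2 ps restrained sampling,
1000 MC steps, local scaling over 10 nearest neighbors, up to 25 clusters,
25 clustering repetitions. Unknown keys are rejected; invalid values raise
a :class:`~replaypose.errors.ValidationError` naming the key.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import InputError, ValidationError
from .replay import ProtocolConfig

__all__ = ["RunConfig", "ProtocolSettings", "PropagatorSettings", "ClusteringSettings", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolSettings(_Strict):
    """Replay-buffer MC parameters (defaults follow the reference protocol)."""

    n_poses: int = Field(default=25, ge=1)
    n_init_replicates: int = Field(default=10, ge=1)
    free_ps: float = Field(default=8.0, gt=0)
    restrained_ps: float = Field(default=2.0, gt=0)
    n_mc_steps: int = Field(default=1000, ge=0)
    restraint_force_constant: float = Field(default=1000.0, ge=0)
    n_energy_samples: int = Field(default=10, ge=1)
    parent_selection: str = Field(default="uniform", pattern="^(uniform|boltzmann)$")
    selection_kt: float = Field(default=1.0, gt=0)

    def to_protocol_config(self, seed: int) -> ProtocolConfig:
        return ProtocolConfig(seed=seed, **self.model_dump())


class PropagatorSettings(_Strict):
    """Toy-propagator parameters (overdamped Langevin)."""

    kind: str = Field(default="toy-langevin", pattern="^toy-langevin$")
    dt: float = Field(default=0.01, gt=0)
    friction: float = Field(default=1.0, gt=0)
    kT: float = Field(default=1.0, ge=0)
    harmonic_k: float = Field(default=1.0, gt=0)  # well stiffness for molecular smoke runs


class ClusteringSettings(_Strict):
    """Self-tuning spectral clustering parameters."""

    k_nn: int = Field(default=10, ge=1)
    k_max: int = Field(default=25, ge=2)
    n_repeats: int = Field(default=25, ge=1)
    n_candidates: int = Field(default=5, ge=1)
    rmsd_selection: Optional[str] = None  # default: all ligand heavy atoms
    align_selection: Optional[str] = None  # default: no superposition
    include_init_in_occupancy: bool = True


class GeometrySpec(_Strict):
    name: str
    atoms: list[str] = Field(min_length=2, max_length=3)


class RunConfig(_Strict):
    """Top-level run configuration (all sections optional in the YAML)."""

    protocol: ProtocolSettings = ProtocolSettings()
    propagator: PropagatorSettings = PropagatorSettings()
    clustering: ClusteringSettings = ClusteringSettings()
    geometry: list[GeometrySpec] = []


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; ``None`` or empty file -> defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such config file: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**raw)
    except pydantic.ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(p) for p in first["loc"])
        raise ValidationError(f"invalid config value for {key!r}: {first['msg']}") from exc


def dump_config(config: RunConfig, path) -> None:
    """Write the fully resolved config; reloads to an identical object."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
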