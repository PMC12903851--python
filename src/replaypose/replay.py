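"""Replay-buffer Monte Carlo engine.

The protocol refines a docked pose set by growing an append-only replay
buffer of configurations with averaged interaction energies:

1. **Initialization** - for each docked pose, ``n_init_replicates``
   independent blocks are run; each block is a free sampling segment
   (default 8 ps) followed by a restrained energy-averaging segment
   (default 2 ps). Every block contributes one buffer entry.
2. **MC loop** - each of ``n_mc_steps`` steps picks a start configuration
   uniformly at random from the current buffer, runs the same
   free-then-restrained block, and appends the result.

There is no acceptance/rejection: every successful step is appended. The
scheme is exploratory - it spreads sampling effort over the basins reachable
from the docked poses - and does **not** target the Boltzmann distribution,
so buffer occupancies are a pose-plausibility measure, not free energies.

With the defaults (25 poses x 10 replicates + 1000 steps) the final buffer
holds exactly 1250 entries.

Per-task seeds are derived from the root seed with a counter-based scheme
keyed on (stage, pose/step index, replicate/attempt), so results do not
depend on execution order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, PropagationError, ValidationError
from .propagation import Propagator, Restraint, SystemState
from .structures import PoseSet

__all__ = [
    "BufferEntry",
    "ReplayBuffer",
    "ProtocolConfig",
    "derive_seed",
    "initialize_buffer",
    "mc_step",
    "run_protocol",
]

logger = logging.getLogger(__name__)

_STAGE_CODES = {"init": 1, "mc": 2, "cluster": 3, "synth": 4}


def derive_seed(root_seed: int, stage: str, *indices: int) -> int:
    """Deterministic per-task seed from a root seed and a (stage, counters) key."""
    entropy = (int(root_seed), _STAGE_CODES.get(stage, 0), *[int(i) for i in indices])
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class ProtocolConfig:
    """Protocol parameters; defaults follow the reference protocol."""

    n_poses: int = 25
    n_init_replicates: int = 10
    free_ps: float = 8.0
    restrained_ps: float = 2.0
    n_mc_steps: int = 1000
    seed: int = 0
    restraint_force_constant: float = 1000.0
    n_energy_samples: int = 10
    parent_selection: str = "uniform"  # "boltzmann" is an off-by-default extension
    selection_kt: float = 1.0  # only used by parent_selection="boltzmann"

    def validate(self) -> "ProtocolConfig":
        if self.n_poses < 1:
            raise ValidationError("n_poses must be >= 1")
        if self.n_init_replicates < 1:
            raise ValidationError("n_init_replicates must be >= 1")
        if self.free_ps <= 0:
            raise ValidationError("free_ps must be > 0")
        if self.restrained_ps <= 0:
            raise ValidationError("restrained_ps must be > 0")
        if self.n_mc_steps < 0:
            raise ValidationError("n_mc_steps must be >= 0")
        if self.n_energy_samples < 1:
            raise ValidationError("n_energy_samples must be >= 1")
        if self.restraint_force_constant < 0:
            raise ValidationError("restraint_force_constant must be >= 0")
        if self.parent_selection not in ("uniform", "boltzmann"):
            raise ValidationError(f"unknown parent_selection {self.parent_selection!r}")
        return self

    def restraint(self) -> Restraint:
        return Restraint(force_constant=self.restraint_force_constant)


@dataclass(frozen=True)
class BufferEntry:
    """One configuration snapshot with its averaged energy and lineage."""

    state: SystemState
    averaged_energy: float
    origin_pose: str
    mc_step: int  # 0 = initialization block
    parent_index: Optional[int] = None

    def __post_init__(self):
        if self.mc_step < 0:
            raise ValidationError("mc_step must be >= 0")
        if (self.parent_index is not None) != (self.mc_step > 0):
            raise ConsistencyError("parent_index must be present iff mc_step > 0")
        if not np.isfinite(self.averaged_energy):
            raise ValidationError("averaged_energy must be finite")


class ReplayBuffer:
    """Append-only ordered store of :class:`BufferEntry`.

    Indices are stable once appended; after initialization with P poses and
    R replicates followed by S MC steps the buffer holds exactly P*R + S
    entries.
    """

    def __init__(self, seed: Optional[int] = None, config: Optional[ProtocolConfig] = None):
        self._entries: list[BufferEntry] = []
        self.seed = seed
        self.config = config

    def append(self, entry: BufferEntry) -> int:
        self._entries.append(entry)
        return len(self._entries) - 1

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, i: int) -> BufferEntry:
        return self._entries[i]

    def __iter__(self):
        return iter(self._entries)

    @property
    def entries(self) -> tuple[BufferEntry, ...]:
        return tuple(self._entries)

    def energies(self) -> np.ndarray:
        return np.array([e.averaged_energy for e in self._entries], dtype=float)

    def coords_array(self) -> np.ndarray:
        """Stack entry coordinates: (n_entries, *coords_shape)."""
        if not self._entries:
            raise ValidationError("empty buffer")
        return np.stack([e.state.coords for e in self._entries])

    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "index": i,
                "origin_pose": e.origin_pose,
                "mc_step": e.mc_step,
                "parent_index": -1 if e.parent_index is None else e.parent_index,
                "averaged_energy": e.averaged_energy,
                "tag": e.state.tag,
            }
            for i, e in enumerate(self._entries)
        ]
        return pd.DataFrame(rows)

    def lineage_is_forest(self) -> bool:
        """True iff every MC entry points to an earlier entry and roots are
        exactly the initialization entries."""
        for i, e in enumerate(self._entries):
            if e.mc_step == 0:
                if e.parent_index is not None:
                    return False
            else:
                p = e.parent_index
                if p is None or not (0 <= p < i):
                    return False
        return True

    # -- serialization (text formats only) ---------------------------------
    def to_dir(self, out_dir, pose_template=None) -> None:
        """Serialize: metadata.csv + states.csv (toy) or states.pdb (molecular)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metadata().to_csv(out / "metadata.csv", index=False)
        coords = self.coords_array()
        info = {
            "n_entries": len(self),
            "coords_shape": list(coords.shape[1:]),
            "seed": self.seed,
            "config": None if self.config is None else vars(self.config),
        }
        if pose_template is not None and coords.ndim == 3 and coords.shape[2] == 3:
            from .structures import PoseSet, write_pose_set

            ps = PoseSet(
                ligand_template=pose_template,
                pose_coords=[c for c in coords],
                pose_ids=[f"entry_{i}" for i in range(len(self))],
            )
            write_pose_set(ps, out / "states.pdb", format="pdb")
            info["states_file"] = "states.pdb"
        else:
            flat = coords.reshape(len(self), -1)
            pd.DataFrame(flat, columns=[f"x{j}" for j in range(flat.shape[1])]).to_csv(
                out / "states.csv", index=False
            )
            info["states_file"] = "states.csv"
        (out / "buffer.json").write_text(json.dumps(info, indent=2))

    @classmethod
    def from_dir(cls, in_dir) -> "ReplayBuffer":
        src = Path(in_dir)
        info = json.loads((src / "buffer.json").read_text())
        meta = pd.read_csv(src / "metadata.csv")
        if info["states_file"] == "states.csv":
            flat = pd.read_csv(src / "states.csv").to_numpy(dtype=float)
            coords = flat.reshape(len(meta), *info["coords_shape"])
        else:
            from .structures import read_pose_set

            ps = read_pose_set(src / "states.pdb", format="pdb")
            coords = np.stack(ps.pose_coords)
        cfg = None
        if info.get("config"):
            cfg = ProtocolConfig(**info["config"])
        buf = cls(seed=info.get("seed"), config=cfg)
        for i, row in meta.iterrows():
            parent = None if row["parent_index"] < 0 else int(row["parent_index"])
            buf.append(
                BufferEntry(
                    state=SystemState(coords=coords[i], tag=str(row["tag"])),
                    averaged_energy=float(row["averaged_energy"]),
                    origin_pose=str(row["origin_pose"]),
                    mc_step=int(row["mc_step"]),
                    parent_index=parent,
                )
            )
        return buf


def _initial_states(poses: PoseSet | Sequence[SystemState]) -> list[tuple[str, SystemState]]:
    if isinstance(poses, PoseSet):
        return [
            (pid, SystemState(coords=xyz, tag=pid))
            for pid, xyz in zip(poses.pose_ids, poses.pose_coords)
        ]
    out = []
    for i, st in enumerate(poses):
        tag = st.tag or f"pose_{i + 1}"
        out.append((tag, SystemState(coords=st.coords, tag=tag)))
    return out


def initialize_buffer(
    poses: PoseSet | Sequence[SystemState],
    receptor,
    config: ProtocolConfig,
    propagator: Propagator,
) -> ReplayBuffer:
    """Seed the replay buffer: R independent free+restrained blocks per pose.

    ``receptor`` is unused by toy propagators and kept for the MD-adapter
    signature. Any propagation failure aborts; partial buffers are never
    returned.
    """
    config.validate()
    starts = _initial_states(poses)
    if not starts:
        raise ValidationError("pose set is empty")
    if len(starts) > config.n_poses:
        starts = starts[: config.n_poses]
    buffer = ReplayBuffer(seed=config.seed, config=config)
    restraint = config.restraint()
    for p_idx, (pose_id, state0) in enumerate(starts):
        for rep in range(config.n_init_replicates):
            seed_free = derive_seed(config.seed, "init", p_idx, rep, 0)
            seed_rest = derive_seed(config.seed, "init", p_idx, rep, 1)
            try:
                mid = propagator.propagate_free(state0, config.free_ps, seed_free)
                result = propagator.propagate_restrained_average(
                    mid, config.restrained_ps, restraint, config.n_energy_samples, seed_rest
                )
            except PropagationError as exc:
                raise PropagationError(
                    f"initialization failed for pose {pose_id!r}, replicate {rep}: {exc}",
                    tag=pose_id,
                ) from exc
            buffer.append(
                BufferEntry(
                    state=result.final_state,
                    averaged_energy=result.averaged_energy,
                    origin_pose=pose_id,
                    mc_step=0,
                    parent_index=None,
                )
            )
    return buffer


def _select_parent(buffer: ReplayBuffer, config: ProtocolConfig, rng: np.random.Generator) -> int:
    n = len(buffer)
    if config.parent_selection == "uniform":
        return int(rng.integers(n))
    # energy-biased extension (off by default): P(i) ~ exp(-E_i / kT_sel)
    e = buffer.energies()
    w = np.exp(-(e - e.min()) / config.selection_kt)
    return int(rng.choice(n, p=w / w.sum()))


def mc_step(
    buffer: ReplayBuffer,
    config: ProtocolConfig,
    propagator: Propagator,
    step_index: int,
) -> BufferEntry:
    """One MC step: pick a parent from the buffer, run a block, append.

    A failed propagation is retried with the next derived seed, at most 3
    attempts, then aborts.
    """
    if len(buffer) == 0:
        raise ValidationError("cannot run an MC step on an empty buffer")
    if step_index < 1:
        raise ValidationError("step_index starts at 1")
    restraint = config.restraint()
    last_exc: Optional[PropagationError] = None
    for attempt in range(3):
        sel_rng = np.random.default_rng(derive_seed(config.seed, "mc", step_index, attempt, 0))
        parent_index = _select_parent(buffer, config, sel_rng)
        parent = buffer[parent_index]
        seed_free = derive_seed(config.seed, "mc", step_index, attempt, 1)
        seed_rest = derive_seed(config.seed, "mc", step_index, attempt, 2)
        try:
            mid = propagator.propagate_free(parent.state, config.free_ps, seed_free)
            result = propagator.propagate_restrained_average(
                mid, config.restrained_ps, restraint, config.n_energy_samples, seed_rest
            )
        except PropagationError as exc:
            last_exc = exc
            logger.warning("MC step %d attempt %d failed: %s", step_index, attempt, exc)
            continue
        entry = BufferEntry(
            state=result.final_state,
            averaged_energy=result.averaged_energy,
            origin_pose=parent.origin_pose,
            mc_step=step_index,
            parent_index=parent_index,
        )
        buffer.append(entry)
        logger.info(
            "mc_step=%d parent=%d energy=%.6g", step_index, parent_index, result.averaged_energy
        )
        return entry
    raise PropagationError(
        f"MC step {step_index} failed after 3 attempts: {last_exc}",
        tag=getattr(last_exc, "tag", None),
    )


def run_protocol(
    poses: PoseSet | Sequence[SystemState],
    receptor,
    config: ProtocolConfig,
    propagator: Propagator,
) -> ReplayBuffer:
    """Full protocol: initialize the buffer, then run ``n_mc_steps`` MC steps."""
    config.validate()
    buffer = initialize_buffer(poses, receptor, config, propagator)
    for step in range(1, config.n_mc_steps + 1):
        mc_step(buffer, config, propagator, step)
    return buffer
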