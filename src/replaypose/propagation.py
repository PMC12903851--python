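"""Propagation contract and the toy overdamped-Langevin propagator.

The Monte Carlo engine only needs two capabilities from a propagator:

* ``propagate_free(state, duration, seed)`` - run an unrestrained sampling
  segment and return the final configuration;
* ``propagate_restrained_average(state, duration, restraint, n_samples,
  seed)`` - run a positionally restrained segment and return the arithmetic
  mean of the interaction-energy observable over ``n_samples`` snapshots
  evenly spaced across it.

In production that contract is met by an MD engine (the restrained segment
averages the ligand-receptor nonbonded interaction energy over solvent
fluctuations). Here it is met by :class:`ToyLangevinPropagator`, an
Euler-Maruyama integrator of overdamped Langevin dynamics

    dx = -(1/gamma) dE/dx dt + sqrt(2 kT dt / gamma) xi

on an analytic landscape. Its stationary distribution, exp(-E/kT), is known
in closed form, which is what makes the full protocol testable against
analytic oracles. Energies are dimensionless landscape units; "ps" durations
are toy time units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, runtime_checkable

import numpy as np

from .errors import PropagationError, ValidationError

__all__ = [
    "SystemState",
    "PropagationResult",
    "Restraint",
    "AnalyticLandscape",
    "GaussianWell",
    "HarmonicWell",
    "ToyLangevinPropagator",
    "Propagator",
    "propagate_free",
    "propagate_restrained_average",
    "landscape_energy",
]


@dataclass
class SystemState:
    """One configuration: coordinates, optional box, RNG token, lineage tag."""

    coords: np.ndarray  # (N, 3) in Angstrom, or a bare D-vector for toy systems
    box: Optional[np.ndarray] = None
    rng_state: Optional[int] = None
    tag: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"non-finite coordinates in state {self.tag!r}")


@dataclass(frozen=True)
class PropagationResult:
    final_state: SystemState
    averaged_energy: float
    n_energy_samples: int

    def __post_init__(self):
        if self.n_energy_samples < 1:
            raise ValidationError("n_energy_samples must be >= 1")
        if not np.isfinite(self.averaged_energy):
            raise PropagationError(
                f"non-finite averaged energy for state {self.final_state.tag!r}",
                tag=self.final_state.tag,
            )


@dataclass(frozen=True)
class Restraint:
    """Harmonic positional restraint anchored at the segment-start positions.

    ``force_constant`` is in energy / length^2 of the propagator's units
    (kJ/mol/nm^2 for an MD adapter, landscape units for the toy). ``indices``
    restricts the restraint to a subset of flattened coordinates; ``None``
    restrains everything (the protocol restrains both protein and ligand).
    """

    force_constant: float
    indices: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValidationError("restraint force constant must be >= 0")


@dataclass(frozen=True)
class GaussianWell:
    """One Gaussian term: -depth * exp(-|x - center|^2 / (2 width^2)).

    Negative ``depth`` yields a barrier (bump) instead of a well.
    """

    center: tuple[float, ...]
    depth: float
    width: float


class AnalyticLandscape:
    """Sum of Gaussian wells/barriers plus a constant offset, with gradient.

    An optional harmonic confinement term ``0.5 * confinement_k * |x|^2``
    emulates the bounded binding-site region: without it, particles that
    escape a well diffuse away forever, which no pocket-bound ligand does.
    ``kT`` records the reference temperature the landscape is meant to be
    sampled at; the propagator reads it as its default temperature.
    """

    def __init__(
        self,
        wells: list[GaussianWell],
        kT: float = 1.0,
        offset: float = 0.0,
        confinement_k: float = 0.0,
    ):
        if kT < 0:
            raise ValidationError("kT must be >= 0")
        if confinement_k < 0:
            raise ValidationError("confinement_k must be >= 0")
        self.wells = list(wells)
        self.kT = float(kT)
        self.offset = float(offset)
        self.confinement_k = float(confinement_k)
        self.dimension = len(wells[0].center) if wells else None
        self._centers = np.array([w.center for w in wells], dtype=float) if wells else None
        self._depths = np.array([w.depth for w in wells], dtype=float) if wells else None
        self._widths = np.array([w.width for w in wells], dtype=float) if wells else None

    def energy(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float).ravel()
        e = self.offset + 0.5 * self.confinement_k * float(x @ x)
        if self._centers is None:
            return e
        d2 = np.sum((x[None, :] - self._centers) ** 2, axis=1)
        return float(e - np.sum(self._depths * np.exp(-d2 / (2.0 * self._widths**2))))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        grad = self.confinement_k * x
        if self._centers is None:
            return grad
        diff = x[None, :] - self._centers  # (W, D)
        d2 = np.sum(diff**2, axis=1)
        g = np.exp(-d2 / (2.0 * self._widths**2))
        # dE/dx = k_conf x + sum_w depth_w * g_w * (x - c_w) / width_w^2
        return grad + np.sum((self._depths * g / self._widths**2)[:, None] * diff, axis=0)


class HarmonicWell:
    """Isotropic harmonic well E = 0.5 k |x - center|^2 (+ offset).

    The canonical mean landscape energy at temperature kT is D*kT/2
    (equipartition), which makes this the oracle landscape for energy
    averaging. ``center`` may have any shape; coordinates are flattened.
    """

    def __init__(self, center, k: float = 1.0, kT: float = 1.0, offset: float = 0.0):
        self.center = np.asarray(center, dtype=float).ravel()
        self.k = float(k)
        self.kT = float(kT)
        self.offset = float(offset)
        self.dimension = self.center.size

    def energy(self, x: np.ndarray) -> float:
        dx = np.asarray(x, dtype=float).ravel() - self.center
        return self.offset + 0.5 * self.k * float(dx @ dx)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.k * (np.asarray(x, dtype=float).ravel() - self.center)


def landscape_energy(landscape, point) -> float:
    """Closed-form energy of an analytic landscape at ``point``."""
    return landscape.energy(np.asarray(point, dtype=float))


@runtime_checkable
class Propagator(Protocol):
    """The propagation contract consumed by the MC engine."""

    def propagate_free(self, state: SystemState, duration: float, seed: int) -> SystemState: ...

    def propagate_restrained_average(
        self,
        state: SystemState,
        duration: float,
        restraint: Restraint,
        n_samples: int,
        seed: int,
    ) -> PropagationResult: ...


@dataclass
class ToyLangevinPropagator:
    """Overdamped Langevin (Euler-Maruyama) on an analytic landscape.

    Parameters
    ----------
    landscape:
        Any object with ``energy(x)`` and ``gradient(x)``.
    kT:
        Temperature in landscape energy units; defaults to the landscape's.
    dt:
        Integrator step in toy time units. The discretization bias of the
        sampled distribution is O(dt * k / gamma); keep ``dt * k / gamma``
        well below 1.
    friction:
        Friction coefficient gamma.
    energy_observable:
        Callable(x) -> float sampled during the restrained segment; defaults
        to the landscape energy itself (the toy stand-in for the
        ligand-receptor interaction energy).
    """

    landscape: object
    kT: Optional[float] = None
    dt: float = 0.01
    friction: float = 1.0
    energy_observable: Optional[object] = None

    def __post_init__(self):
        if self.kT is None:
            self.kT = float(getattr(self.landscape, "kT", 1.0))
        if self.dt <= 0 or self.friction <= 0:
            raise ValidationError("dt and friction must be > 0")
        if self.energy_observable is None:
            self.energy_observable = self.landscape.energy

    # -- internals ---------------------------------------------------------
    def _steps(self, duration: float) -> int:
        if duration <= 0:
            raise ValidationError("duration must be > 0")
        return max(1, int(round(duration / self.dt)))

    def _advance(self, x, rng, n_steps, dt, anchor=None, k_restraint=0.0, restraint_idx=None,
                 sample_at=(), observable=None, tag=""):
        noise_scale = np.sqrt(2.0 * self.kT * dt / self.friction)
        sample_at = set(sample_at)
        samples = []
        for step in range(1, n_steps + 1):
            force = -self.landscape.gradient(x)
            if anchor is not None and k_restraint > 0:
                pull = np.zeros_like(x)
                if restraint_idx is None:
                    pull = -k_restraint * (x - anchor)
                else:
                    idx = np.asarray(restraint_idx, dtype=int)
                    pull[idx] = -k_restraint * (x[idx] - anchor[idx])
                force = force + pull
            x = x + (dt / self.friction) * force
            if self.kT > 0:
                x = x + noise_scale * rng.standard_normal(x.shape)
            if not np.all(np.isfinite(x)):
                raise PropagationError(f"propagation diverged for state {tag!r}", tag=tag)
            if step in sample_at:
                e = float(observable(x))
                if not np.isfinite(e):
                    raise PropagationError(f"non-finite energy sample for state {tag!r}", tag=tag)
                samples.append(e)
        return x, samples

    # -- contract ----------------------------------------------------------
    def propagate_free(self, state: SystemState, duration: float, seed: int) -> SystemState:
        n_steps = self._steps(duration)
        rng = np.random.default_rng(seed)
        shape = state.coords.shape
        x, _ = self._advance(state.coords.ravel().copy(), rng, n_steps, self.dt, tag=state.tag)
        return SystemState(coords=x.reshape(shape), box=state.box, rng_state=seed, tag=state.tag)

    def propagate_restrained_average(
        self,
        state: SystemState,
        duration: float,
        restraint: Restraint,
        n_samples: int = 10,
        seed: int = 0,
    ) -> PropagationResult:
        if n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        # Euler-Maruyama is only stable for dt * k / gamma well below 2; a
        # stiff restraint therefore forces substepping (dt * k_r / gamma <= 0.2)
        dt = self.dt
        if restraint.force_constant > 0:
            dt = min(dt, 0.2 * self.friction / restraint.force_constant)
        n_steps = max(1, int(round(duration / dt)))
        # snapshots evenly spaced over the segment, last one at the end
        sample_at = sorted({max(1, round(j * n_steps / n_samples)) for j in range(1, n_samples + 1)})
        rng = np.random.default_rng(seed)
        shape = state.coords.shape
        x0 = state.coords.ravel().copy()
        x, samples = self._advance(
            x0,
            rng,
            n_steps,
            dt,
            anchor=x0,
            k_restraint=restraint.force_constant,
            restraint_idx=restraint.indices,
            sample_at=sample_at,
            observable=self.energy_observable,
            tag=state.tag,
        )
        final = SystemState(coords=x.reshape(shape), box=state.box, rng_state=seed, tag=state.tag)
        return PropagationResult(
            final_state=final,
            averaged_energy=float(np.mean(samples)),
            n_energy_samples=len(samples),
        )


def propagate_free(state: SystemState, duration: float, propagator: Propagator, seed: int) -> SystemState:
    """Run an unrestrained sampling segment (free 8 ps leg of each block)."""
    return propagator.propagate_free(state, duration, seed)


def propagate_restrained_average(
    state: SystemState,
    duration: float,
    restraint: Restraint,
    n_samples: int,
    propagator: Propagator,
    seed: int,
) -> PropagationResult:
    """Run the restrained energy-averaging segment (final 2 ps leg)."""
    return propagator.propagate_restrained_average(state, duration, restraint, n_samples, seed)
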