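"""Langevin dynamics in reduced units (BAOAB splitting).

The equations of motion are integrated with the BAOAB discretization of
underdamped Langevin dynamics: half kick, half drift, exact
Ornstein-Uhlenbeck velocity update, half drift, half kick.  With the
friction set to zero the O step is the identity and the scheme reduces
exactly to velocity Verlet, which is what the microcanonical (NVE)
energy-drift checks exercise.  With friction gamma* = 1 the stationary
kinetic temperature matches the target T* with O(dt^2) bias.

All randomness flows through a single ``numpy.random.Generator`` whose
state is captured in checkpoints, so an interrupted run restarted from a
checkpoint reproduces the uninterrupted trajectory bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import (
    ForceFieldParams,
    build_pair_lists,
    compute_forces,
    evaluate,
)
from .topology import Frame, MolecularSystem, Species, wrap_positions

__all__ = [
    "SimulationState",
    "SimulationResult",
    "IntegrationError",
    "init_velocities",
    "langevin_step",
    "run_simulation",
    "kinetic_temperature",
]


class IntegrationError(RuntimeError):
    """Raised when the integration becomes unstable (NaN coordinates)."""


@dataclass
class SimulationState:
    """Complete integrator state for checkpoint/restart."""

    positions: np.ndarray
    velocities: np.ndarray
    step: int
    rng_state: dict

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.positions.copy(), self.velocities.copy(), self.step, dict(self.rng_state)
        )


@dataclass
class SimulationResult:
    frames: list[Frame]
    sample_steps: np.ndarray
    temperatures: np.ndarray  # instantaneous kinetic T* at sample steps
    potential_energies: np.ndarray
    kinetic_energies: np.ndarray
    final_state: SimulationState = field(repr=False)

    @property
    def mean_temperature(self) -> float:
        return float(self.temperatures.mean()) if len(self.temperatures) else math.nan


def kinetic_temperature(velocities: np.ndarray, mass: float) -> float:
    """Instantaneous kinetic temperature T* = m <v^2> / 3."""
    n = velocities.shape[0]
    return float(mass * np.sum(velocities**2) / (3.0 * n))


def init_velocities(
    n: int, T_star: float, mass: float, rng: np.random.Generator
) -> np.ndarray:
    """Maxwell-Boltzmann velocities with the center-of-mass drift removed."""
    v = rng.normal(scale=math.sqrt(T_star / mass), size=(n, 3))
    if n > 1:
        v -= v.mean(axis=0)
    return v


def langevin_step(
    positions: np.ndarray,
    velocities: np.ndarray,
    forces: np.ndarray,
    box_L: float,
    is_tail: np.ndarray,
    charge: np.ndarray,
    bonds: np.ndarray,
    params: ForceFieldParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One BAOAB step; returns (positions, velocities, forces, energy).

    ``forces`` must be the forces at the input positions (reused from the
    previous step); the returned forces correspond to the new positions.
    """
    dt = params.dt_star
    m = params.mass
    gamma = params.gamma_star

    v = velocities + 0.5 * dt * forces / m
    x = positions + 0.5 * dt * v
    if gamma > 0.0:
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt((1.0 - c1 * c1) * params.T_star / m)
        v = c1 * v + c2 * rng.standard_normal(size=v.shape)
    x = x + 0.5 * dt * v
    x = wrap_positions(x, box_L)
    energy, f = compute_forces(x, box_L, is_tail, charge, bonds, params)
    v = v + 0.5 * dt * f / m
    return x, v, f, energy


def run_simulation(
    system: MolecularSystem,
    frame0: Frame,
    params: ForceFieldParams,
    n_steps: int,
    seed: int = 0,
    dump_stride: int = 0,
    sample_stride: int = 50,
    state: SimulationState | None = None,
    skin: float = 0.4,
) -> SimulationResult:
    """Integrate ``n_steps`` of Langevin dynamics.

    Parameters
    ----------
    dump_stride : emit a trajectory Frame every this many steps (0 = only
        the initial and final frames).
    sample_stride : record temperature/energy samples at this interval.
    state : resume from a checkpointed :class:`SimulationState` instead of
        drawing fresh initial velocities; the run then continues the
        uninterrupted trajectory bitwise.
    skin : Verlet-list skin (sigma); lists are rebuilt once any bead has
        moved further than skin/2 since the last build, so the evaluated
        forces are exact regardless of the skin.

    With ``n_steps == 0`` the initial frame alone is returned.
    """
    is_tail = (system.species == Species.SURFACTANT_TAIL).astype(np.uint8)
    charge = system.charge.astype(np.float64)
    bonds = system.bonds
    L = frame0.box_L

    rng = np.random.default_rng(seed)
    if state is None:
        x = wrap_positions(np.array(frame0.positions, dtype=np.float64), L)
        v = init_velocities(system.n_beads, params.T_star, params.mass, rng)
        step0 = frame0.step
    else:
        x = state.positions.copy()
        v = state.velocities.copy()
        step0 = state.step
        rng.bit_generator.state = state.rng_state

    frames = [Frame(x.copy(), L, step0)]
    samples, temps, epots, ekins = [], [], [], []
    if n_steps == 0:
        final = SimulationState(x, v, step0, rng.bit_generator.state)
        return SimulationResult(
            frames, np.array(samples), np.array(temps), np.array(epots),
            np.array(ekins), final,
        )

    lists = build_pair_lists(x, L, charge, params, skin=skin)
    _, f = evaluate(x, L, is_tail, charge, bonds, params, lists)
    dt = params.dt_star
    m = params.mass
    gamma = params.gamma_star
    if gamma > 0.0:
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt((1.0 - c1 * c1) * params.T_star / m)
    half_skin2 = (skin / 2.0) ** 2
    for k in range(1, n_steps + 1):
        # BAOAB step with neighbor-list reuse
        v = v + 0.5 * dt * f / m
        x = x + 0.5 * dt * v
        if gamma > 0.0:
            v = c1 * v + c2 * rng.standard_normal(size=v.shape)
        x = x + 0.5 * dt * v
        x = wrap_positions(x, L)
        d = x - lists.built_at
        d -= L * np.round(d / L)
        if np.max(np.einsum("ij,ij->i", d, d)) > half_skin2:
            lists = build_pair_lists(x, L, charge, params, skin=skin)
        epot, f = evaluate(x, L, is_tail, charge, bonds, params, lists)
        v = v + 0.5 * dt * f / m
        step = step0 + k
        if k % sample_stride == 0 or k == n_steps:
            if not np.all(np.isfinite(x)):
                raise IntegrationError(f"non-finite coordinates at step {step}")
            temps.append(kinetic_temperature(v, params.mass))
            epots.append(epot)
            ekins.append(0.5 * params.mass * float(np.sum(v**2)))
            samples.append(step)
        if dump_stride and k % dump_stride == 0:
            frames.append(Frame(x.copy(), L, step))
    if not dump_stride:
        frames.append(Frame(x.copy(), L, step0 + n_steps))

    final = SimulationState(x.copy(), v.copy(), step0 + n_steps, rng.bit_generator.state)
    return SimulationResult(
        frames,
        np.array(samples),
        np.array(temps),
        np.array(epots),
        np.array(ekins),
        final,
    )
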