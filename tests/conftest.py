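"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from moundsim import ModelParameters, PopulationState, forces


@pytest.fixture
def params() -> ModelParameters:
    return ModelParameters()


def make_state(positions, velocities=None, is_rich=None, time=0.0) -> PopulationState:
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if velocities is None:
        velocities = np.zeros((n, 2))
    if is_rich is None:
        is_rich = np.zeros(n, dtype=bool)
    return PopulationState(time, positions, np.asarray(velocities, dtype=float),
                           np.asarray(is_rich, dtype=bool), np.arange(n))


def random_state(n, rng, radius=100.0, speed=5.0, n_rich=0) -> PopulationState:
    pos = rng.uniform(-radius, radius, size=(n, 2))
    vel = rng.normal(0.0, speed, size=(n, 2))
    is_rich = np.arange(n) < n_rich
    return make_state(pos, vel, is_rich)


def brute_force_neighbors(positions, radius) -> list[np.ndarray]:
    """All-pairs O(n²) neighbour search; the oracle for the k-d tree path."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    out = []
    for i in range(n):
        d = np.hypot(*(positions - positions[i]).T)
        out.append(np.array([j for j in range(n) if j != i and d[j] <= radius],
                            dtype=int))
    return out


def naive_step(state: PopulationState, params: ModelParameters) -> PopulationState:
    """Per-cell Euler step built from the pure force functions.

    Independent of the simulator's vectorised path; used to cross-check it.
    """
    n = state.n_cells
    new_pos = np.empty_like(state.positions)
    new_vel = np.empty_like(state.velocities)
    for i in range(n):
        d = np.hypot(*(state.positions - state.positions[i]).T)
        local = [j for j in range(n) if j != i and d[j] <= params.l_loc]
        contact = [j for j in range(n) if j != i and d[j] <= params.l_cont]
        rich = bool(state.is_rich[i])
        f = (forces.central_force(state.positions[i],
                                  params.k_cent * (params.w_cent if rich else 1.0))
             + forces.contact_following_force(
                 [state.velocities[j] for j in contact],
                 params.k_cont * (params.w_cont if rich else 1.0))
             + forces.repulsion_force(state.positions[i],
                                      [state.positions[j] for j in local],
                                      params))
        alpha = forces.resistance_coefficient(len(local), params)
        new_vel[i] = forces.net_velocity(f, alpha)
        new_pos[i] = state.positions[i] + new_vel[i] * params.dt
    return PopulationState(state.time + params.dt, new_pos, new_vel,
                           state.is_rich.copy(), state.cell_ids.copy())


def rotate(points, angle):
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    return np.asarray(points, dtype=float) @ rot.T
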