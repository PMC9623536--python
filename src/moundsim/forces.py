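"""Force terms and drag coefficient of the mound-phase cell-motion model.

The model is an overdamped force balance: for cell *i*,

    α_i v_i = F_cent + F_cont + F_rep,

where α_i is a density-dependent drag and the three forces are

* a **central force** of constant magnitude directed at the mound centre
  (the origin), modelling the response to cAMP signals propagating from
  the centre;
* a **contact-following force** of constant magnitude along the direction
  of the summed velocities of contact neighbours (within ``l_cont``),
  which produces collective rotation;
* a **soft repulsion** between local neighbours (within ``l_loc``), linear
  in the overlap, modelling volume exclusion.

These are pure per-cell reference implementations; the simulator uses an
equivalent vectorised path that is cross-checked against these functions
in the test suite.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .params import ModelParameters

#: Pair distances below this are treated as coincident cells; their
#: repulsion contribution is skipped since no direction is defined.
COINCIDENCE_TOL = 1e-9


def resistance_coefficient(n_local_neighbors: int | np.ndarray,
                           params: ModelParameters) -> float | np.ndarray:
    """Density-dependent drag α = α₀ + β·nᵠ/(mᵠ + nᵠ).

    The Hill-form second term makes the drag rise from α₀ in isolation
    towards (but never reaching) α₀ + β in dense neighbourhoods, with
    half-saturation at ``m`` neighbours and steepness ``q``.

    Parameters
    ----------
    n_local_neighbors : int or array of int
        Number of cells within ``l_loc`` of the focal cell (excluding it).
    """
    n = np.asarray(n_local_neighbors, dtype=float)
    if np.any(n < 0):
        raise ValueError("neighbor count must be non-negative")
    nq = n ** params.q
    alpha = params.alpha0 + params.beta * nq / (params.m ** params.q + nq)
    return float(alpha) if np.isscalar(n_local_neighbors) else alpha


def central_force(position: Sequence[float], k_eff: float) -> np.ndarray:
    """Constant-magnitude force pointing from ``position`` to the origin.

    Returns the zero vector when the cell sits exactly at the centre,
    where the direction is undefined.
    """
    if k_eff < 0:
        raise ValueError("k_eff must be >= 0")
    pos = np.asarray(position, dtype=float)
    r = np.hypot(pos[0], pos[1])
    if r == 0.0:
        return np.zeros(2)
    return -k_eff * pos / r


def contact_following_force(contact_velocities: Sequence[Sequence[float]],
                            k_eff: float) -> np.ndarray:
    """Force of magnitude ``k_eff`` along the summed contact-neighbour velocities.

    ``contact_velocities`` are the velocities of all cells within ``l_cont``
    of the focal cell (the focal cell excluded). If there are no contacts,
    or the velocities cancel exactly, the force is zero.
    """
    if k_eff < 0:
        raise ValueError("k_eff must be >= 0")
    if len(contact_velocities) == 0:
        return np.zeros(2)
    vsum = np.sum(np.asarray(contact_velocities, dtype=float), axis=0)
    norm = np.hypot(vsum[0], vsum[1])
    if norm == 0.0:
        return np.zeros(2)
    return k_eff * vsum / norm


def repulsion_force(focal_position: Sequence[float],
                    neighbor_positions: Sequence[Sequence[float]],
                    params: ModelParameters) -> np.ndarray:
    """Volume-exclusion force pushing the focal cell away from local neighbours.

    Each neighbour within ``l_loc`` contributes a force along the line from
    the neighbour to the focal cell with magnitude
    ``k_rep · (l_loc − d) / l_loc``, vanishing continuously at ``d = l_loc``.
    Coincident pairs (d < COINCIDENCE_TOL) are skipped.
    """
    focal = np.asarray(focal_position, dtype=float)
    total = np.zeros(2)
    for nb in neighbor_positions:
        diff = focal - np.asarray(nb, dtype=float)
        d = np.hypot(diff[0], diff[1])
        if d < COINCIDENCE_TOL or d > params.l_loc:
            continue
        total += params.k_rep * (params.l_loc - d) / params.l_loc * diff / d
    return total


def net_velocity(total_force: Sequence[float], alpha: float) -> np.ndarray:
    """Overdamped velocity F/α resulting from the force balance."""
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return np.asarray(total_force, dtype=float) / alpha
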