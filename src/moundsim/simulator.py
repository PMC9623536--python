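"""Euler time-stepping of the mound model and the two simulation protocols.

Two protocols are provided:

* the **sorting protocol**: all cells (ATP-rich and ATP-poor) are scattered
  uniformly over a disc with zero velocity and stepped for the full run,
  during which collective rotation emerges and ATP-rich cells sort to the
  mound centre;
* the **invasion protocol**: a rotating mound is first established with
  ATP-poor cells only, then ATP-rich "invader" cells are introduced at the
  mound periphery and their inward spiral towards the centre is followed.

Positions and velocities are recorded on a uniform grid (1 min by default)
into a :class:`TrajectorySet`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .forces import COINCIDENCE_TOL
from .params import ModelParameters

RICH = "rich"
POOR = "poor"

_TINY = 1e-300  # guards 0/0 in unit-vector computations; masked out afterwards


@dataclass
class PopulationState:
    """Positions, velocities and class labels of all cells at one time."""

    time: float
    positions: np.ndarray      # (n, 2) float, μm
    velocities: np.ndarray     # (n, 2) float, μm·min⁻¹
    is_rich: np.ndarray        # (n,) bool
    cell_ids: np.ndarray       # (n,) int, unique and stable over a run

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.velocities) == len(self.is_rich) == len(self.cell_ids) == n):
            raise ValueError("inconsistent state array lengths")
        if len(np.unique(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique")

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.time, self.positions.copy(), self.velocities.copy(),
            self.is_rich.copy(), self.cell_ids.copy(),
        )


@dataclass
class TrajectorySet:
    """Recorded positions of all cells on a uniform time grid.

    ``positions[t, i]`` is NaN for frames before cell *i* was introduced
    (relevant only for the invasion protocol).
    """

    record_times: np.ndarray   # (T,) min, strictly increasing, uniform
    positions: np.ndarray      # (T, n, 2) μm, NaN before introduction
    cell_ids: np.ndarray       # (n,) int
    is_rich: np.ndarray        # (n,) bool
    params: ModelParameters

    @property
    def record_interval(self) -> float:
        return float(self.record_times[1] - self.record_times[0])

    def radii(self, center=(0.0, 0.0)) -> np.ndarray:
        """Radial distance of every cell from ``center`` at every record time, (T, n)."""
        d = self.positions - np.asarray(center, dtype=float)
        return np.hypot(d[..., 0], d[..., 1])

    def frame(self, time: float) -> tuple[np.ndarray, np.ndarray]:
        """Positions and rich-mask of cells present at the record time nearest ``time``."""
        idx = int(np.argmin(np.abs(self.record_times - time)))
        pos = self.positions[idx]
        present = np.isfinite(pos[:, 0])
        return pos[present], self.is_rich[present]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: time_min, cell_id, cell_class, x_um, y_um (time-major, then cell_id)."""
        T, n, _ = self.positions.shape
        order = np.argsort(self.cell_ids)
        rows = []
        cls = np.where(self.is_rich, RICH, POOR)
        for t_idx in range(T):
            pos = self.positions[t_idx]
            for i in order:
                if np.isfinite(pos[i, 0]):
                    rows.append((self.record_times[t_idx], self.cell_ids[i],
                                 cls[i], pos[i, 0], pos[i, 1]))
        return pd.DataFrame(rows, columns=["time_min", "cell_id", "cell_class",
                                           "x_um", "y_um"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def initialize_population(params: ModelParameters,
                          rng: np.random.Generator) -> PopulationState:
    """Scatter ``n_cells`` cells uniformly over the initial disc, at rest.

    The first ``n_rich`` cell ids carry the ATP-rich label; since positions
    are i.i.d. this is equivalent to labelling a random subset.
    """
    n = params.n_cells
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    r = params.init_radius * np.sqrt(rng.uniform(0.0, 1.0, size=n))
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    is_rich = np.arange(n) < params.n_rich
    return PopulationState(
        time=0.0,
        positions=positions,
        velocities=np.zeros((n, 2)),
        is_rich=is_rich,
        cell_ids=np.arange(n),
    )


def find_neighbors(state: PopulationState, radius: float) -> list[np.ndarray]:
    """Index sets of cells within ``radius`` of each cell (self excluded).

    Uses a k-d tree; the relation is symmetric and the boundary (distance
    exactly equal to ``radius``) is included.
    """
    if not radius > 0:
        raise ValueError("radius must be > 0")
    tree = cKDTree(state.positions)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    out: list[list[int]] = [[] for _ in range(state.n_cells)]
    for i, j in pairs:
        out[i].append(j)
        out[j].append(i)
    return [np.array(sorted(s), dtype=int) for s in out]


def _pairs_within(tree: cKDTree, radius: float) -> np.ndarray:
    return tree.query_pairs(radius, output_type="ndarray").reshape(-1, 2)


def step(state: PopulationState, params: ModelParameters) -> PopulationState:
    """One synchronous Euler step of Δt.

    All neighbour sets and forces are evaluated on the input state, so the
    update is order-independent. The contact-following force uses the
    velocities from the previous step (zero at t = 0), hence the first step
    is driven purely by the central and repulsion forces.
    """
    pos = state.positions
    vel = state.velocities
    n = state.n_cells

    tree = cKDTree(pos)
    pairs = _pairs_within(tree, params.l_loc)
    pi, pj = pairs[:, 0], pairs[:, 1]
    diff = pos[pi] - pos[pj]
    dist = np.hypot(diff[:, 0], diff[:, 1])

    # local density for the drag term (coincident cells still count)
    counts = (np.bincount(pi, minlength=n) + np.bincount(pj, minlength=n)).astype(float)
    nq = counts ** params.q
    alpha = params.alpha0 + params.beta * nq / (params.m ** params.q + nq)

    # pairwise soft repulsion, antisymmetric by construction
    f_rep = np.zeros_like(pos)
    ok = dist >= COINCIDENCE_TOL
    if np.any(ok):
        w = params.k_rep * (params.l_loc - dist[ok]) / (params.l_loc * dist[ok])
        contrib = diff[ok] * w[:, None]
        np.add.at(f_rep, pi[ok], contrib)
        np.add.at(f_rep, pj[ok], -contrib)

    # contact-following along the summed neighbour velocities
    if params.l_cont <= params.l_loc:
        cmask = dist <= params.l_cont
        ci, cj = pi[cmask], pj[cmask]
    else:
        cpairs = _pairs_within(tree, params.l_cont)
        ci, cj = cpairs[:, 0], cpairs[:, 1]
    vsum = np.zeros_like(pos)
    np.add.at(vsum, ci, vel[cj])
    np.add.at(vsum, cj, vel[ci])
    vnorm = np.hypot(vsum[:, 0], vsum[:, 1])
    k_cont = params.k_cont * np.where(state.is_rich, params.w_cont, 1.0)
    f_cont = np.where(
        (vnorm > 0.0)[:, None],
        k_cont[:, None] * vsum / np.maximum(vnorm, _TINY)[:, None],
        0.0,
    )

    # constant-magnitude pull towards the mound centre (the origin)
    r = np.hypot(pos[:, 0], pos[:, 1])
    k_cent = params.k_cent * np.where(state.is_rich, params.w_cent, 1.0)
    f_cent = np.where(
        (r > 0.0)[:, None],
        -k_cent[:, None] * pos / np.maximum(r, _TINY)[:, None],
        0.0,
    )

    new_vel = (f_cent + f_cont + f_rep) / alpha[:, None]
    new_pos = pos + new_vel * params.dt
    if not np.all(np.isfinite(new_pos)):
        raise FloatingPointError(
            f"non-finite positions at t={state.time + params.dt:.2f} min: "
            "numerical blow-up (check dt and force magnitudes)"
        )
    return PopulationState(
        time=state.time + params.dt,
        positions=new_pos,
        velocities=new_vel,
        is_rich=state.is_rich,
        cell_ids=state.cell_ids,
    )


def _steps_per_record(params: ModelParameters) -> int:
    k = params.record_interval / params.dt
    k_int = int(round(k))
    if abs(k - k_int) > 1e-9:
        raise ValueError("record_interval must be an integer multiple of dt")
    return k_int


def _run_recorded(state: PopulationState, params: ModelParameters,
                  t_final: float, record: list[np.ndarray],
                  times: list[float],
                  stop_fn=None) -> PopulationState:
    """Step ``state`` to ``t_final``, appending a frame every record interval."""
    k = _steps_per_record(params)
    t0 = state.time
    n_records = int(round((t_final - t0) / params.record_interval))
    for i in range(n_records):
        for _ in range(k):
            state = step(state, params)
        # snap to the exact record grid; Δt accumulation drifts at float
        # precision over thousands of steps
        state.time = t0 + (i + 1) * params.record_interval
        record.append(state.positions.copy())
        times.append(state.time)
        if stop_fn is not None and stop_fn(state):
            break
    return state


def run_sorting_protocol(params: ModelParameters) -> TrajectorySet:
    """Full-population run: scatter all cells over the disc and step for ``duration``.

    Records every ``record_interval`` minutes, including the initial frame,
    so a 300-min run at 1-min recording yields 301 frames.
    """
    rng = np.random.default_rng(params.seed)
    state = initialize_population(params, rng)
    frames = [state.positions.copy()]
    times = [0.0]
    _run_recorded(state, params, params.duration, frames, times)
    return TrajectorySet(
        record_times=np.array(times),
        positions=np.array(frames),
        cell_ids=state.cell_ids.copy(),
        is_rich=state.is_rich.copy(),
        params=params,
    )


def _place_invaders(state: PopulationState, n_invaders: int,
                    rng: np.random.Generator,
                    edge_quantile: float = 0.95) -> PopulationState:
    """Append rich invaders at the mound periphery, at rest.

    The periphery radius is the ``edge_quantile`` quantile of the resident
    cells' radial distances at the introduction time; invader angles are
    uniform.
    """
    radii = np.hypot(state.positions[:, 0], state.positions[:, 1])
    r_edge = float(np.quantile(radii, edge_quantile))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_invaders)
    inv_pos = np.column_stack([r_edge * np.cos(theta), r_edge * np.sin(theta)])
    next_id = int(state.cell_ids.max()) + 1
    return PopulationState(
        time=state.time,
        positions=np.vstack([state.positions, inv_pos]),
        velocities=np.vstack([state.velocities, np.zeros((n_invaders, 2))]),
        is_rich=np.concatenate([state.is_rich, np.ones(n_invaders, dtype=bool)]),
        cell_ids=np.concatenate([state.cell_ids,
                                 np.arange(next_id, next_id + n_invaders)]),
    )


def _invasion_phase1(params: ModelParameters, n_invaders: int,
                     pre_rotation_time: float):
    """Poor-only pre-rotation phase; returns (state, rng, frames, times)."""
    rng = np.random.default_rng(params.seed)
    p1 = params.with_(n_cells=params.n_cells - n_invaders, n_rich=0)
    state = initialize_population(p1, rng)
    frames = [state.positions.copy()]
    times = [0.0]
    state = _run_recorded(state, p1, pre_rotation_time, frames, times)
    return state, rng, frames, times


def run_invasion_protocol(params: ModelParameters,
                          n_invaders: int = 10,
                          pre_rotation_time: float = 120.0,
                          stop_radius: float | None = None) -> TrajectorySet:
    """Two-phase run: establish rotation with ATP-poor cells, then add invaders.

    Phase 1 runs ``n_cells − n_invaders`` ATP-poor cells for
    ``pre_rotation_time`` minutes to produce collective rotational motion.
    Phase 2 introduces ``n_invaders`` ATP-rich cells at the mound periphery
    with zero velocity and continues until ``params.duration``. Invader
    records begin at the introduction frame; earlier frames hold NaN.

    If ``stop_radius`` is given, the run stops early once every invader has
    been recorded inside that radius (arrival times are unaffected since
    they are first-crossing times).
    """
    if not pre_rotation_time > 0:
        raise ValueError("pre_rotation_time must be > 0")
    if n_invaders < 1:
        raise ValueError("n_invaders must be >= 1")
    if pre_rotation_time >= params.duration:
        raise ValueError("pre_rotation_time must be < duration")

    state, rng, frames, times = _invasion_phase1(params, n_invaders,
                                                 pre_rotation_time)
    return _invasion_phase2(state, rng, frames, times, params, n_invaders,
                            stop_radius)


def _invasion_phase2(state: PopulationState, rng: np.random.Generator,
                     frames: list[np.ndarray], times: list[float],
                     params: ModelParameters, n_invaders: int,
                     stop_radius: float | None) -> TrajectorySet:
    n_resident = state.n_cells
    state = _place_invaders(state, n_invaders, rng)
    # widen the already recorded phase-1 frames with NaN invader slots; the
    # introduction-time frame is re-recorded with the invaders present
    frames = [
        np.vstack([f, np.full((n_invaders, 2), np.nan)]) for f in frames
    ]
    frames[-1] = state.positions.copy()

    if stop_radius is not None:
        arrived = np.zeros(n_invaders, dtype=bool)

        def stop_fn(s: PopulationState) -> bool:
            inv = s.positions[n_resident:]
            arrived[np.hypot(inv[:, 0], inv[:, 1]) <= stop_radius] = True
            return bool(arrived.all())
    else:
        stop_fn = None

    _run_recorded(state, params, params.duration, frames, times, stop_fn)
    return TrajectorySet(
        record_times=np.array(times),
        positions=np.array(frames),
        cell_ids=state.cell_ids.copy(),
        is_rich=state.is_rich.copy(),
        params=params,
    )


@dataclass
class ArrivalTimes:
    """First-arrival times of ATP-rich cells at the mound-centre region.

    ``times`` holds, per rich cell, the elapsed minutes from its
    introduction to the first recorded frame inside ``center_radius``
    (NaN if the cell never arrives within the run).
    """

    cell_ids: np.ndarray
    times: np.ndarray
    center_radius: float

    @property
    def n_arrived(self) -> int:
        return int(np.sum(np.isfinite(self.times)))

    @property
    def n_cells(self) -> int:
        return len(self.times)

    @property
    def mean(self) -> float:
        """Mean first-arrival time; NaN (undefined) if any cell never arrived."""
        if self.n_arrived < self.n_cells:
            return float("nan")
        return float(np.mean(self.times))

    @property
    def mean_of_arrived(self) -> float:
        """Mean over the cells that did arrive (NaN if none did)."""
        if self.n_arrived == 0:
            return float("nan")
        return float(np.nanmean(self.times))


def time_to_center(traj: TrajectorySet,
                   center_radius: float | None = None) -> ArrivalTimes:
    """Per-rich-cell elapsed time from introduction to first frame in the centre.

    The centre region is the disc of ``center_radius`` (default: the run's
    ``params.center_radius``) around the origin; arrival is assessed on the
    record grid, so a crossing between records is attributed to the first
    record inside the region.
    """
    if center_radius is None:
        center_radius = traj.params.center_radius
    rich = np.flatnonzero(traj.is_rich)
    if len(rich) == 0:
        raise ValueError("trajectory contains no ATP-rich cells")
    radii = traj.radii()[:, rich]            # (T, n_rich)
    finite = np.isfinite(radii)
    times = np.full(len(rich), np.nan)
    for k in range(len(rich)):
        present = np.flatnonzero(finite[:, k])
        intro = present[0]
        inside = np.flatnonzero(radii[present, k] <= center_radius)
        if len(inside):
            times[k] = traj.record_times[present[inside[0]]] - traj.record_times[intro]
    return ArrivalTimes(cell_ids=traj.cell_ids[rich], times=times,
                        center_radius=float(center_radius))


@dataclass
class SweepResult:
    """Arrival-time summaries over a grid of relative force magnitudes."""

    table: pd.DataFrame          # one row per (w_cent, w_cont, seed)
    per_cell: pd.DataFrame       # one row per invader per run

    def mean_arrival(self, w_cent: float, w_cont: float) -> float:
        """Mean over seeds of the per-run mean arrival time."""
        sub = self.table[(self.table.w_cent == w_cent)
                         & (self.table.w_cont == w_cont)]
        return float(sub.arrival_time_min.mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.4f")


def sweep_forces(params: ModelParameters,
                 w_cent_values, w_cont_values,
                 n_seeds: int = 1,
                 n_invaders: int = 10,
                 pre_rotation_time: float = 120.0,
                 stop_early: bool = True) -> SweepResult:
    """Invasion-protocol arrival times over a (w_cent, w_cont) grid.

    For each seed the poor-only pre-rotation phase is identical across grid
    points (the invaders' placement draws follow all initialisation draws),
    so it is computed once per seed and re-used. ``arrival_time_min`` is the
    mean first-arrival time of the invaders that reached the centre region;
    ``n_arrived`` out of ``n_invaders`` reports completeness.
    """
    w_cent_values = list(w_cent_values)
    w_cont_values = list(w_cont_values)
    if not w_cent_values or not w_cont_values:
        raise ValueError("w_cent_values and w_cont_values must be nonempty")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")

    rows = []
    cell_rows = []
    for s in range(n_seeds):
        seed = params.seed + s
        base = params.with_(seed=seed)
        state1, rng, frames1, times1 = _invasion_phase1(
            base, n_invaders, pre_rotation_time)
        rng_state = rng.bit_generator.state
        for wc in w_cent_values:
            for wt in w_cont_values:
                p = base.with_(w_cent=wc, w_cont=wt)
                rng2 = np.random.default_rng()
                rng2.bit_generator.state = rng_state
                traj = _invasion_phase2(
                    state1.copy(), rng2, list(frames1), list(times1), p,
                    n_invaders,
                    stop_radius=p.center_radius if stop_early else None)
                arr = time_to_center(traj)
                rows.append((wc, wt, seed, arr.mean_of_arrived,
                             arr.n_arrived, n_invaders))
                for cid, t in zip(arr.cell_ids, arr.times):
                    cell_rows.append((wc, wt, seed, int(cid), t))
    table = pd.DataFrame(rows, columns=["w_cent", "w_cont", "seed",
                                        "arrival_time_min", "n_arrived",
                                        "n_invaders"])
    per_cell = pd.DataFrame(cell_rows, columns=["w_cent", "w_cont", "seed",
                                                "cell_id",
                                                "arrival_time_min"])
    return SweepResult(table=table, per_cell=per_cell)
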