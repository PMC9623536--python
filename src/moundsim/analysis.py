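"""Trajectory and intensity statistics for tracked mound-phase cells.

Works on both simulated trajectories and externally tracked cells supplied
as a tidy CSV (columns ``cell_id, time_min, x_um, y_um`` plus an optional
``intensity``). The statistics mirror how tracked cells are analysed:
per-minute migration speed, decomposition of each displacement into a
centripetal component (positive toward the mound centre) and a tangential
component, standardisation of fluorescence intensities, the rich/poor
classification at ±0.5 standardised units, Pearson correlation with a
two-sided significance test, and ordinary least-squares fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

RICH = "rich"
POOR = "poor"
UNCLASSIFIED = "unclassified"

_CENTER_TOL = 1e-12


@dataclass
class Track:
    """A single cell's positions at a fixed sampling interval.

    ``intensity`` is an optional scalar fluorescence readout (arbitrary
    units, one value per cell); ``class_label`` an optional ground-truth or
    assigned rich/poor label.
    """

    cell_id: int
    positions: np.ndarray          # (T, 2) μm
    sampling_interval: float = 1.0  # min
    intensity: float | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (T, 2)")
        if len(self.positions) < 2:
            raise ValueError("a track needs at least 2 positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be > 0")


@dataclass(frozen=True)
class VelocityDecomposition:
    """Mean centripetal (signed, positive inward) and tangential (magnitude) speeds."""

    centripetal_speed: float   # μm·min⁻¹, > 0 means net motion toward the centre
    tangential_speed: float    # μm·min⁻¹, ≥ 0


def standardize_intensities(intensities) -> np.ndarray:
    """Scale intensities to (X − μ)/σ with the population σ (divide by n).

    The scaled values have mean 0 and population standard deviation 1, the
    convention under which the ±0.5 rich/poor thresholds are defined.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 intensities")
    sd = x.std()  # population convention
    if sd == 0:
        raise ValueError("intensities have zero spread; cannot standardize")
    return (x - x.mean()) / sd


def classify_by_intensity(standardized_intensity: float) -> str:
    """Rich above +0.5, poor below −0.5, unclassified in between (inclusive)."""
    if standardized_intensity > 0.5:
        return RICH
    if standardized_intensity < -0.5:
        return POOR
    return UNCLASSIFIED


def migration_speed(track: Track) -> float:
    """Mean per-interval displacement magnitude over the sampling interval.

    With per-minute sampling this is the average of the per-minute migration
    distances D_i (μm·min⁻¹).
    """
    disp = np.diff(track.positions, axis=0)
    d = np.hypot(disp[:, 0], disp[:, 1])
    return float(d.mean() / track.sampling_interval)


def decompose_velocity(track: Track, center=(0.0, 0.0)) -> VelocityDecomposition:
    """Split each displacement into centripetal and tangential components.

    For every sampling interval the displacement is projected onto the
    inward radial unit vector at the interval's start point (centripetal,
    positive toward the centre) and onto its perpendicular (tangential,
    reported as a magnitude). The per-interval components are averaged and
    divided by the sampling interval. Intervals starting exactly at the
    centre have no defined radial direction and are skipped.
    """
    center = np.asarray(center, dtype=float)
    rel = track.positions - center
    disp = np.diff(track.positions, axis=0)
    start = rel[:-1]
    r = np.hypot(start[:, 0], start[:, 1])
    ok = r > _CENTER_TOL
    if not np.any(ok):
        raise ValueError("track is entirely at the centre; "
                         "radial direction undefined")
    inward = -start[ok] / r[ok, None]
    v_c = np.einsum("ij,ij->i", disp[ok], inward)
    # perpendicular of the inward unit vector; sign discarded below
    v_t = np.abs(disp[ok, 0] * inward[:, 1] - disp[ok, 1] * inward[:, 0])
    dt = track.sampling_interval
    return VelocityDecomposition(
        centripetal_speed=float(v_c.mean() / dt),
        tangential_speed=float(v_t.mean() / dt),
    )


def pearson_correlation(x, y, alpha: float = 0.05) -> tuple[float, bool]:
    """Sample Pearson r with a two-sided significance flag at level ``alpha``.

    Significance uses the exact two-sided test for zero correlation (the
    t-distribution behind the standard critical-value table).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate spread; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), bool(res.pvalue < alpha)


def linear_fit(x, y) -> tuple[float, float]:
    """Ordinary least-squares slope and intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must have equal length >= 2")
    if x.std() == 0:
        raise ValueError("x has zero spread; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def speed_vs_radius_profile(traj, center=(0.0, 0.0),
                            t_start: float = 0.0, t_end: float | None = None,
                            bin_width: float = 10.0) -> pd.DataFrame:
    """Binned mean moving speed as a function of distance from the centre.

    Every record interval within [t_start, t_end] contributes, per cell,
    the pair (radial distance at the interval start, displacement magnitude
    over the record interval). Samples are binned by radius and averaged.

    Returns a DataFrame with columns ``radius_mid`` (bin midpoint, μm),
    ``mean_speed_um_min`` and ``n_samples``, ordered by radius.
    """
    times = traj.record_times
    if t_end is None:
        t_end = float(times[-1])
    if not t_start < t_end:
        raise ValueError("t_start must be < t_end")
    sel = np.flatnonzero((times >= t_start) & (times <= t_end))
    if len(sel) < 2:
        raise ValueError("time window contains fewer than 2 record frames")
    center = np.asarray(center, dtype=float)
    dt = traj.record_interval

    pos = traj.positions[sel]                       # (Tw, n, 2)
    rel = pos[:-1] - center
    radius = np.hypot(rel[..., 0], rel[..., 1]).ravel()
    disp = np.diff(pos, axis=0)
    speed = (np.hypot(disp[..., 0], disp[..., 1]) / dt).ravel()
    finite = np.isfinite(radius) & np.isfinite(speed)
    radius, speed = radius[finite], speed[finite]

    bins = np.floor(radius / bin_width).astype(int)
    df = pd.DataFrame({"bin": bins, "speed": speed})
    grouped = df.groupby("bin")["speed"].agg(["mean", "size"]).reset_index()
    return pd.DataFrame({
        "radius_mid": (grouped["bin"] + 0.5) * bin_width,
        "mean_speed_um_min": grouped["mean"],
        "n_samples": grouped["size"],
    }).sort_values("radius_mid", ignore_index=True)


def rotational_order(positions_before: np.ndarray, positions_after: np.ndarray,
                     center=(0.0, 0.0)) -> float:
    """Mean signed alignment of cell displacements with the local tangent.

    For each moving cell, the cosine between its displacement direction and
    the counterclockwise tangential direction about ``center`` contributes
    with its sign; +1 means uniform counterclockwise rotation, −1 uniform
    clockwise, ≈0 incoherent motion. Stationary cells (and cells at the
    centre) carry no directional information and are excluded.
    """
    p0 = np.asarray(positions_before, dtype=float)
    p1 = np.asarray(positions_after, dtype=float)
    rel = p0 - np.asarray(center, dtype=float)
    disp = p1 - p0
    r = np.hypot(rel[:, 0], rel[:, 1])
    d = np.hypot(disp[:, 0], disp[:, 1])
    ok = (r > _CENTER_TOL) & (d > 0)
    if not np.any(ok):
        raise ValueError("no moving cells; rotational order undefined")
    # counterclockwise tangent at (x, y) is (−y, x)/r
    cosang = (-rel[ok, 1] * disp[ok, 0] + rel[ok, 0] * disp[ok, 1]) / (r[ok] * d[ok])
    return float(cosang.mean())


def sorting_index(positions: np.ndarray, is_rich: np.ndarray,
                  center=(0.0, 0.0), k: int | None = None) -> float:
    """Fraction of the k centre-nearest cells that are ATP-rich.

    With k equal to the number of rich cells (the default), 1.0 means every
    rich cell sits strictly inside every poor cell — sorting complete — and
    a well-mixed population scores about the rich fraction.
    """
    positions = np.asarray(positions, dtype=float)
    is_rich = np.asarray(is_rich, dtype=bool)
    n = len(positions)
    if k is None:
        k = int(is_rich.sum())
    if not 1 <= k <= n:
        raise ValueError("k must be in [1, n_cells]")
    rel = positions - np.asarray(center, dtype=float)
    r = np.hypot(rel[:, 0], rel[:, 1])
    nearest = np.argsort(r, kind="stable")[:k]
    return float(is_rich[nearest].mean())


# ---------------------------------------------------------------------------
# Track CSV input / per-cell statistics output

def read_tracks(path) -> list[Track]:
    """Read tracks from a tidy CSV (cell_id, time_min, x_um, y_um[, intensity]).

    The sampling interval is inferred from the time stamps and validated to
    be uniform across every track.
    """
    df = pd.read_csv(path)
    required = {"cell_id", "time_min", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    has_intensity = "intensity" in df.columns
    tracks = []
    interval = None
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("time_min")
        steps = np.diff(g["time_min"].to_numpy(dtype=float))
        if len(steps) == 0:
            raise ValueError(f"cell {cid} has a single time point")
        if not np.allclose(steps, steps[0]):
            raise ValueError(f"cell {cid} is not uniformly sampled")
        if interval is None:
            interval = float(steps[0])
        elif not np.isclose(interval, steps[0]):
            raise ValueError("tracks have inconsistent sampling intervals")
        intensity = float(g["intensity"].iloc[0]) if has_intensity else None
        tracks.append(Track(cell_id=int(cid),
                            positions=g[["x_um", "y_um"]].to_numpy(dtype=float),
                            sampling_interval=interval,
                            intensity=intensity))
    return tracks


def estimate_center(tracks: list[Track]) -> np.ndarray:
    """Time-averaged centroid of all tracked positions (fallback mound centre)."""
    allpos = np.vstack([t.positions for t in tracks])
    return allpos.mean(axis=0)


def analyze_tracks(tracks: list[Track], center=None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-cell statistics table for a set of tracks.

    Standardises intensities (when present), classifies cells at the ±0.5
    thresholds, and computes the migration speed and the velocity
    decomposition about ``center`` (estimated as the time-averaged centroid
    of all positions when not supplied). Columns: ``cell_id,
    intensity_std, class, speed_um_min, v_centripetal, v_tangential``.
    """
    if not tracks:
        raise ValueError("no tracks to analyze")
    if center is None:
        center = estimate_center(tracks)
    have_intensity = all(t.intensity is not None for t in tracks)
    if have_intensity:
        z = standardize_intensities([t.intensity for t in tracks])
        labels = [classify_by_intensity(v) for v in z]
    else:
        z = np.full(len(tracks), np.nan)
        labels = [t.class_label or UNCLASSIFIED for t in tracks]
    rows = []
    for track, zi, lab in zip(tracks, z, labels):
        dec = decompose_velocity(track, center)
        rows.append((track.cell_id, zi, lab, migration_speed(track),
                     dec.centripetal_speed, dec.tangential_speed))
    return pd.DataFrame(rows, columns=["cell_id", "intensity_std", "class",
                                       "speed_um_min", "v_centripetal",
                                       "v_tangential"])
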