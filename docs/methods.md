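# Methods

## The model

`moundsim` simulates the mound stage of *Dictyostelium discoideum*
development, in which ~10³–10⁵ aggregated amoebae rotate collectively about
the mound centre while cells destined to become prestalk cells — here
identified with ATP-rich cells — migrate against that bulk flow to the
centre. Each cell *i* is a point agent in an unbounded two-dimensional
plane, with position **x**ᵢ (μm) and velocity **v**ᵢ (μm·min⁻¹). Inertia is
neglected (cell motion at this scale is deeply overdamped), so the velocity
follows instantaneously from a force balance:

    αᵢ vᵢ = F_cent + F_cont + F_rep

with three active force terms:

* **Central force** `F_cent = −k_cent · x̂ᵢ`: a constant-magnitude pull
  toward the mound centre, fixed at the origin. This stands in for directed
  migration in response to cAMP signals propagating outward from the
  centre; the signal field itself is not modelled. The force is zero
  exactly at the origin, where the direction is undefined.
* **Contact-following force**
  `F_cont = k_cont · Σ_{j∈C} v_j / |Σ_{j∈C} v_j|`, where *C* is the set of
  cells within the contact radius `l_cont` of cell *i* (excluding *i*).
  Cells push in the common heading of the cells they touch, which is the
  mechanism that turns many locally aligned cells into a globally rotating
  mound. If the neighbour velocities sum to zero (including the no-contact
  case) the force is zero.
* **Repulsion** `F_rep = k_rep · Σ_{j∈M} (l_loc − d_ij)/l_loc · (x̂ᵢⱼ)`:
  soft volume exclusion, linear in the pair overlap within the local
  radius `l_loc`, vanishing continuously at `d = l_loc`. *M* is the local
  neighbour set (cells within `l_loc`, excluding *i*).

The drag coefficient rises with local crowding in Hill form,

    αᵢ = α₀ + β·|M|^q / (m^q + |M|^q),

from α₀ for an isolated cell toward (never reaching) α₀+β in a dense
neighbourhood, with half-saturation at m neighbours and steepness q.

ATP-rich cells differ from ATP-poor cells only through two dimensionless
factors: their central force is `k_cent·w_cent` (w_cent > 1: stronger pull
to the centre) and their contact-following force `k_cont·w_cont`
(w_cont ≤ 1: weaker coupling to the bulk flow). Drag and repulsion make no
class distinction.

### Parameters

| name | default | units | meaning |
|------|---------|-------|---------|
| k_cent | 3.4 | ng·μm·min⁻² | central-force magnitude (poor cells) |
| k_cont | 18 | ng·μm·min⁻² | contact-following magnitude (poor cells) |
| k_rep | 7.2 | ng·μm·min⁻² | maximum pairwise repulsion |
| l_loc | 15 | μm | local-neighbourhood radius (repulsion, drag) |
| l_cont | 10 | μm | contact radius (following) |
| α₀, β | 1, 5 | ng·min⁻¹ | baseline and density-dependent drag |
| m, q | 30, 6 | – | Hill midpoint and exponent of the drag law |
| w_cent, w_cont | 1.5, 1.0 | – | rich-cell force factors |
| dt | 0.1 | min | Euler time step |
| n_cells, n_rich | 1000, 100 | – | population composition |
| init_radius | 150 | μm | radius of the initial scatter disc |
| center_radius | 50 | μm | "mound centre" region for arrival times |
| duration | 300 | min | simulated time |
| record_interval | 1 | min | trajectory recording grid |

The physical constants are the published parameterisation of this model;
they were chosen by its authors to reproduce microscopy, not measured.
`init_radius` is not part of that set: we scatter cells over a 150-μm disc,
which compacts into a mound of roughly 110 μm radius, of the same order as
the 100-μm scale bars in the published stills, and keeps initial local
neighbourhoods populated. The mound's equilibrium size and density are
emergent (central force vs. repulsion), not imposed.

### Integration and protocols

Time is discretised at Δt = 0.1 min and integrated with the forward Euler
method, synchronously: all neighbour sets and forces are evaluated on the
pre-step state, then v(t+Δt) = F/α and x(t+Δt) = x(t) + v(t+Δt)·Δt for
every cell at once, so the result is independent of cell order. The
velocity entering contact-following at step t is the one computed in the
previous step (zero at t = 0); the first step is therefore driven purely
by the central and repulsion forces. Neighbour queries use a k-d tree
(`scipy.spatial.cKDTree`); the test suite checks it against a brute-force
all-pairs scan, and the vectorised update against a per-cell evaluation
built from the pure force functions. Coincident cells (pair distance
< 10⁻⁹ μm) contribute no repulsion — any direction would be arbitrary, and
the event has probability zero under the initialiser — but still count
toward the drag density. Positions are recorded every minute on an exact
time grid (record times are computed as multiples of the interval, not by
accumulating Δt, which drifts at float precision over thousands of steps).

Two protocols:

* **Sorting**: all 1000 cells (100 rich) scattered uniformly over the
  disc, at rest, stepped for 5 h. Rotation emerges from the incoherent
  transient and rich cells sort toward the centre.
* **Invasion**: 990 poor cells rotate for 2 h; then invader rich cells
  (default 10) are placed at the mound periphery — uniformly random angles
  at the 95th percentile of the resident cells' radial distances, at rest —
  and the run continues. Per invader, the arrival time is the elapsed time
  from introduction to the first recorded frame within `center_radius` of
  the origin. One seeded generator drives each run; invader placement
  draws come after all initialisation draws, so the resident phase is
  identical across invader configurations at a given seed, and the sweep
  over (w_cent, w_cont) grids re-uses it. If any invader never arrives the
  mean arrival time is reported as undefined (NaN), with the count of
  arrived cells alongside.

## Trajectory statistics

For a track sampled at interval Δ (1 min for both the simulation recorder
and the tracked-cell convention), the migration speed is the mean
per-interval displacement magnitude divided by Δ. The velocity
decomposition projects each displacement onto the inward radial unit
vector at the interval's start point (centripetal component, signed,
positive toward the centre) and its perpendicular (tangential component,
reported as a magnitude, since the rotation sense is arbitrary); per
interval the two components satisfy the Pythagorean identity with the
interval speed exactly. Intervals starting exactly at the centre are
skipped. Fluorescence intensities are standardised to (X−μ)/σ with the
population σ (the scaling treats μ, σ as distribution parameters); cells
above +0.5 are classified ATP-rich, below −0.5 ATP-poor, the rest
unclassified. Pearson correlations use the standard sample estimator with
an exact two-sided t-test for significance (level 0.05 by default —
equivalent to the critical-value table at that level); line fits are
ordinary least squares.

Two summary statistics operationalise qualitative observations:

* **rotational order**: the mean over moving cells of the signed cosine
  between each cell's displacement and the local counterclockwise tangent
  about the centre; +1/−1 for uniform counter-/clockwise rotation, ≈0 for
  incoherent motion.
* **sorting index**: the fraction of the k cells nearest the centre that
  are rich, with k the number of rich cells; 1 means every rich cell lies
  strictly inside every poor cell, and a well-mixed population scores the
  rich fraction (0.1 at the defaults).

The speed–radius profile assigns to each record interval and cell the pair
(radius at interval start, displacement/Δ), then bins by radius (10 μm
default) and averages.

## Synthetic tracks

The fixture generator produces purely kinematic tracks with known ground
truth: per interval the cell advances by v_c·Δ along the inward radial
direction and v_t·Δ along the tangent, with v_c, v_t drawn fresh from
class-dependent Gaussians. The default means and spreads are the measured
group statistics of tracked mound cells (centripetal 8.8 ± 3.0 μm·min⁻¹
for rich vs 5.4 ± 5.3 for poor; tangential 11.0 ± 4.2 vs 15.4 ± 5.9), with
200 tracks per class, 30 min at 1-min sampling. Intensities are Gaussian
at ±1.0 (σ 0.3) so that a balanced sample standardises to values clearing
the ±0.5 classification thresholds. Start radii are uniform in
300–400 μm: far enough out that 30 min of inward motion at the rich mean
(≈264 μm plus noise) cannot reach the centre, where the radial direction
degenerates; as a guard, radii are floored at 1 μm. A rigid-rotation
frame-pair generator (chord displacement 2·r·sin(ωΔ/2)) provides the
closed-form test bed for the rotational-order and speed-profile
statistics.

What these fixtures deliberately lack: cell–cell interactions, curvature
of real trajectories within an interval, intensity measurement noise
correlated with position, and track gaps. Passing the round-trip tests
therefore shows that the estimators are unbiased for displacement fields
of this form, not that they are robust to tracking artefacts.

## Numerical choices and degenerate cases

* Zero-direction cases are defined to return exactly zero force: the
  central force at the origin and the contact force for an empty or
  cancelling velocity sum.
* `time_to_center` is assessed on the 1-min record grid; a crossing
  between records is attributed to the first record inside the region.
* The arrival sweep stops a run early once every invader has been recorded
  inside the centre region; first-crossing times are unaffected.
* A non-finite position aborts the run with a diagnostic; at the default
  parameters no instability occurs over 5 simulated hours.
* Reported sweep and sorting summaries use 5 seeds per condition; a full
  1000-cell, 5-h run takes a few seconds on one CPU core.

## Observed behaviour and limitations

At the defaults the model reproduces the reported invasion arrival times
to well within a factor of 1.5 on every grid point, with the reported
orderings (larger w_cent → faster; smaller w_cont → faster) strict. In the
sorting protocol, rich cells end well inside poor cells by 3 h (mean radii
≈ 22 vs 67 μm), matching the published configuration; the k-nearest
sorting index, however, saturates near 0.85 rather than 1 — rich and poor
cells interleave inside the dense core, because nothing in the model
expels a poor cell that reached the centre early. Coordinated rotation
emerges after a shorter incoherent transient (≈5–30 min) than the ~30 min
reported; the transient length depends on the initial scatter density,
which the published parameter set does not pin down. Occasionally (≈1 in 5
seeds) the mound settles into counter-rotating domains and never reaches
global coherence; sorting still completes in the radial sense. The
speed–radius profile rises strictly through the mound body but dips by
1–2% in the sparse fringe beyond the 95th-percentile radius, where cells
have few contact neighbours.

Not modelled: cAMP wave propagation and chemotaxis dynamics, cell division
and death, three-dimensional structure (the real mound sorts vertically as
well), boundaries (cohesion comes entirely from the central force), and
any feedback of position on ATP state.
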