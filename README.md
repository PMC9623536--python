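# moundsim

Agent-based simulation and trajectory analysis of collective rotational
cell motion and ATP-dependent cell sorting in the *Dictyostelium
discoideum* mound.

During the mound stage of *Dictyostelium* development, aggregated cells
rotate collectively about the mound centre while a subpopulation with high
intracellular ATP migrates *against* that bulk flow to the central tip
region, where prestalk fate is determined. `moundsim` implements a
two-dimensional overdamped force-balance model of this process and the
track statistics used to characterise it, for modellers and
quantitative cell biologists who want to reproduce and explore the sorting
behaviour.

## Model

Each cell obeys an overdamped force balance

```
αᵢ vᵢ = F_cent + F_cont + F_rep
```

* `F_cent = −k_cent x̂ᵢ` — constant-magnitude pull toward the mound centre
  (the origin), standing in for cAMP-guided migration;
* `F_cont = k_cont Σ_{j∈Cᵢ} vⱼ / |Σ_{j∈Cᵢ} vⱼ|` — contact following: a push
  of fixed magnitude along the common heading of the cells within the
  contact radius `l_cont`, the ingredient that produces collective
  rotation;
* `F_rep = k_rep Σ_{j∈Mᵢ} (l_loc − d)/l_loc · x̂ᵢⱼ` — soft volume exclusion
  between cells within `l_loc`;
* `αᵢ = α₀ + β|Mᵢ|^q/(m^q + |Mᵢ|^q)` — drag rising in Hill form with local
  crowding.

ATP-rich cells carry a stronger central force (`k_cent·w_cent`, w_cent>1)
and optionally a weaker contact-following force (`k_cont·w_cont`,
w_cont≤1); this asymmetry alone sorts them to the centre. The analysis
module provides the matching track statistics: per-minute migration speed,
the centripetal/tangential velocity decomposition about the mound centre,
intensity standardisation with ±0.5 rich/poor classification, Pearson
correlation with significance, OLS fits, a rotational-order parameter and
a k-nearest-centre sorting index. A fixture module generates synthetic
tracks with known class-dependent speed distributions so every statistic
is testable without microscopy data.

See `docs/methods.md` for the full model description, parameter table,
numerical choices and known limitations.

## Worked example

```python
import numpy as np
from moundsim import (ModelParameters, run_sorting_protocol, sorting_index,
                      rotational_order, sweep_forces)

params = ModelParameters(seed=0)          # w_cent=1.5, w_cont=1.0
traj = run_sorting_protocol(params)       # 1000 cells, 5 simulated hours

pos, rich = traj.frame(180.0)
r = np.hypot(*pos.T)
i = int(np.argmin(np.abs(traj.record_times - 180.0)))
print(f"sorting index at 3 h:      {sorting_index(pos, rich):.2f}")
print(f"mean radius rich / poor:   {r[rich].mean():.0f} / {r[~rich].mean():.0f} um")
print(f"rotational order at 3 h:   {rotational_order(traj.positions[i], traj.positions[i+1]):+.2f}")

sweep = sweep_forces(params, [1.5, 3.0], [1.0, 0.5], n_seeds=3)
for (wc, wt), grp in sweep.table.groupby(["w_cent", "w_cont"]):
    print(f"w_cent={wc}, w_cont={wt}: mean arrival {grp.arrival_time_min.mean():5.1f} min")
```

prints

```
sorting index at 3 h:      0.54
mean radius rich / poor:   22 / 66 um
rotational order at 3 h:   +0.97
w_cent=1.5, w_cont=0.5: mean arrival  46.8 min
w_cent=1.5, w_cont=1.0: mean arrival  78.7 min
w_cent=3.0, w_cont=0.5: mean arrival  14.0 min
w_cent=3.0, w_cont=1.0: mean arrival  16.4 min
```

By 3 h the ATP-rich cells sit well inside the ATP-poor cells (mean radii
22 vs 66 μm) while the mound rotates coherently (order +0.97; the sign is
the arbitrary rotation sense). The sweep reruns the invasion protocol —
2 h of rotation with ATP-poor cells only, then 10 ATP-rich invaders placed
at the mound periphery — and reports how long the invaders take to reach
the 50-μm centre region: a stronger central force (w_cent 1.5 → 3.0) and a
weaker contact-following force (w_cont 1.0 → 0.5) both speed up arrival.

The same runs are available from the shell:

```bash
moundsim simulate --seed 0 --outdir run1           # sorting protocol
moundsim invade --seed 0 --wcent 3.0 --outdir run2 # invasion protocol
moundsim sweep --wcent 1.5,3.0 --wcont 1.0,0.5 --seeds 3 --outdir run3
moundsim synth --seed 1 --out tracks.csv           # synthetic tracks
moundsim analyze tracks.csv --center 0,0 --out stats.csv
```

Every output directory contains the effective configuration and seed
needed to regenerate it byte for byte.

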