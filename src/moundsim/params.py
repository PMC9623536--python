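"""Model parameters for the mound-phase cell-motion model.

All lengths are in micrometres, all times in minutes, force magnitudes in
ng·μm·min⁻² and drag coefficients in ng·min⁻¹ throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace


@dataclass(frozen=True)
class ModelParameters:
    """Physical and numerical constants of the mound model plus run settings.

    The defaults are the published parameterisation of the model: a mound of
    1000 cells (100 ATP-rich, 900 ATP-poor) driven by a constant-magnitude
    central force, a contact-following force along the mean heading of
    contact neighbours, a linear soft-core repulsion, and a density-dependent
    drag of Hill form.

    Attributes
    ----------
    k_cent : float
        Central-force magnitude of ATP-poor cells (ng·μm·min⁻²).
    k_cont : float
        Contact-following force magnitude of ATP-poor cells (ng·μm·min⁻²).
    k_rep : float
        Maximum pairwise repulsion magnitude (ng·μm·min⁻²).
    l_loc : float
        Local-neighbourhood radius for repulsion and drag (μm).
    l_cont : float
        Contact radius for the contact-following force (μm).
    alpha0 : float
        Baseline drag coefficient (ng·min⁻¹).
    beta : float
        Density-dependent drag amplitude (ng·min⁻¹); the drag saturates
        towards ``alpha0 + beta`` at high local density.
    m, q : float
        Hill midpoint (neighbour count at half-saturation) and exponent of
        the drag law.
    w_cent, w_cont : float
        Relative central / contact-following force magnitudes of ATP-rich
        cells (ATP-poor cells always use factor 1).
    dt : float
        Euler time step (min).
    n_cells, n_rich : int
        Total population size and number of ATP-rich cells.
    init_radius : float
        Radius of the disc over which cells are initially scattered (μm).
    center_radius : float
        Radius defining the "mound centre" region for arrival times (μm).
    duration : float
        Simulated time per run (min).
    record_interval : float
        Interval between recorded frames (min).
    seed : int
        Seed of the run's random generator.
    """

    k_cent: float = 3.4
    k_cont: float = 18.0
    k_rep: float = 7.2
    l_loc: float = 15.0
    l_cont: float = 10.0
    alpha0: float = 1.0
    beta: float = 5.0
    m: float = 30.0
    q: float = 6.0
    w_cent: float = 1.5
    w_cont: float = 1.0
    dt: float = 0.1
    n_cells: int = 1000
    n_rich: int = 100
    init_radius: float = 150.0
    center_radius: float = 50.0
    duration: float = 300.0
    record_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "k_cont", "k_rep", "l_loc", "l_cont", "alpha0", "beta",
            "dt", "init_radius", "center_radius", "duration",
            "record_interval",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.k_cent < 0:
            raise ValueError(f"k_cent must be >= 0, got {self.k_cent}")
        if self.q < 1:
            raise ValueError(f"q must be >= 1, got {self.q}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.w_cent < 0 or self.w_cont < 0:
            raise ValueError("w_cent and w_cont must be >= 0")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if not 0 <= self.n_rich <= self.n_cells:
            raise ValueError(
                f"n_rich must lie in [0, n_cells], got {self.n_rich}"
            )
        if self.record_interval < self.dt:
            raise ValueError("record_interval must be >= dt")

    def with_(self, **overrides) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))
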