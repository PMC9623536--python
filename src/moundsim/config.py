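"""Run configuration: flat key = value files with validated defaults.

A run configuration is the full set of model parameters plus protocol
settings. The file format is one ``key = value`` pair per line, ``#``
comments allowed; unknown keys are rejected and missing keys take the
published defaults. The effective configuration is echoed into every
output directory so a run can be regenerated from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .params import ModelParameters

PROTOCOLS = ("sorting", "invasion", "sweep")


@dataclass
class RunConfig:
    """Model parameters plus protocol selection and run bookkeeping."""

    params: ModelParameters = field(default_factory=ModelParameters)
    protocol: str = "sorting"
    n_invaders: int = 10
    pre_rotation_time: float = 120.0
    w_cent_values: tuple[float, ...] = (1.0, 1.5, 3.0)
    w_cont_values: tuple[float, ...] = (1.0, 0.5)
    n_seeds: int = 1
    outdir: str = "moundsim_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}, "
                             f"got {self.protocol!r}")
        if self.n_invaders < 1:
            raise ValueError("n_invaders must be >= 1")
        if not self.pre_rotation_time > 0:
            raise ValueError("pre_rotation_time must be > 0")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if not self.w_cent_values or not self.w_cont_values:
            raise ValueError("sweep grids must be nonempty")


_PARAM_FIELDS = {f.name: f.type for f in fields(ModelParameters)}
_INT_PARAMS = {"n_cells", "n_rich", "seed"}
_CONFIG_FIELDS = {"protocol", "n_invaders", "pre_rotation_time",
                  "w_cent_values", "w_cont_values", "n_seeds", "outdir",
                  "log_level"}


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key in ("w_cent_values", "w_cont_values"):
        return tuple(float(v) for v in raw.split(",") if v.strip())
    if key in ("protocol", "outdir", "log_level"):
        return raw
    if key in _INT_PARAMS or key in ("n_invaders", "n_seeds"):
        return int(raw)
    return float(raw)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from an optional file plus overrides.

    Overrides (e.g. command-line flags) take precedence over the file;
    every unset key keeps the published default. Unknown keys and
    out-of-range values raise a descriptive ``ValueError``.
    """
    settings: dict = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', "
                                 f"got {line!r}")
            key, raw = (s.strip() for s in line.split("=", 1))
            settings[key] = raw
    if overrides:
        settings.update({k: v for k, v in overrides.items() if v is not None})

    param_kwargs: dict = {}
    config_kwargs: dict = {}
    for key, raw in settings.items():
        value = _parse_value(key, raw) if isinstance(raw, str) else raw
        if key in _PARAM_FIELDS:
            param_kwargs[key] = (int(value) if key in _INT_PARAMS
                                 else value)
        elif key in _CONFIG_FIELDS:
            config_kwargs[key] = value
        else:
            raise ValueError(f"unknown configuration key: {key!r}")
    return RunConfig(params=ModelParameters(**param_kwargs), **config_kwargs)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Echo the effective configuration as a re-loadable key = value file."""
    lines = [f"{f.name} = {getattr(config.params, f.name)}"
             for f in fields(ModelParameters)]
    lines += [
        f"protocol = {config.protocol}",
        f"n_invaders = {config.n_invaders}",
        f"pre_rotation_time = {config.pre_rotation_time}",
        "w_cent_values = " + ",".join(str(v) for v in config.w_cent_values),
        "w_cont_values = " + ",".join(str(v) for v in config.w_cont_values),
        f"n_seeds = {config.n_seeds}",
        f"log_level = {config.log_level}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
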