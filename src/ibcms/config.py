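"""TOML run configuration.

Units at the configuration surface are CGS (cm, s, g) except where the
clinical convention is explicitly mmHg: the port keys ``pressure_mmhg``
and ``resistance`` (mmHg s/cm^3).  Indices are 0-based; positions are
physical cell-centered coordinates in cm.

Example::

    [grid]
    ndim = 2
    n = [64, 64]
    extent = [16.0, 16.0]

    [fluid]
    rho = 1.0
    nu = 0.03125
    dt = 2.44140625e-5

    [run]
    fixture = "ventricle2d"     # or fiber_file = "model"  (CSV stem)
    cycle_period = 0.8
    transient = 0.2
    n_cycles = 1
    field_cadence = 1024        # steps between field snapshots (0 = none)
    out = "run.h5"

    [[port]]
    name = "PV"
    center = [7.3, 10.8]
    radius = 0.5
    pressure_mmhg = 15.0
    resistance = 1.2
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .core_fluid import FluidParams, GridSpec
from .sources import ReservoirPort

__all__ = ["RunConfig", "load_config", "dump_config"]

_FIXTURES = ("ventricle2d", "ellipse", "cylinder", "ellipsoid3d", "none")


@dataclass
class RunConfig:
    """Validated run configuration (see the module docstring for units)."""

    grid: GridSpec
    fluid: FluidParams
    ports: list = field(default_factory=list)
    fixture: str = "ventricle2d"
    fiber_file: str | None = None
    cycle_period: float = 0.8
    transient: float = 0.2
    n_cycles: int = 1
    field_cadence: int = 0
    checkpoint_cadence: int = 0
    out: str = "run.h5"
    fixture_options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fixture not in _FIXTURES:
            raise ValueError(
                f"unknown fixture '{self.fixture}'; choose from {_FIXTURES}"
            )
        if self.fixture == "none" and not self.fiber_file:
            raise ValueError("fixture 'none' requires fiber_file")
        if self.cycle_period <= 0 or self.transient < 0 or self.n_cycles < 1:
            raise ValueError("invalid run timing")

    @property
    def n_steps_per_cycle(self) -> int:
        return int(round(self.cycle_period / self.fluid.dt))

    def to_json(self) -> str:
        d = {
            "grid": {"ndim": self.grid.ndim, "n": list(self.grid.n),
                     "extent": list(self.grid.extent)},
            "fluid": {k: v for k, v in asdict(self.fluid).items()},
            "ports": [
                {"name": p.name, "center": list(p.center), "radius": p.radius,
                 "pressure_mmhg": p.reservoir_pressure,
                 "resistance": p.resistance,
                 "smoothing_time": p.smoothing_time}
                for p in self.ports
            ],
            "run": {
                "fixture": self.fixture, "fiber_file": self.fiber_file,
                "cycle_period": self.cycle_period, "transient": self.transient,
                "n_cycles": self.n_cycles,
                "field_cadence": self.field_cadence,
                "checkpoint_cadence": self.checkpoint_cadence,
                "out": self.out,
                "fixture_options": self.fixture_options,
            },
        }
        return json.dumps(d, sort_keys=True)


def _ports_from_list(items) -> list:
    ports = []
    for it in items:
        ports.append(
            ReservoirPort(
                name=it["name"],
                center=tuple(it["center"]),
                radius=float(it["radius"]),
                reservoir_pressure=float(it["pressure_mmhg"]),
                resistance=float(it["resistance"]),
                smoothing_time=float(it.get("smoothing_time", 0.01)),
            )
        )
    return ports


def load_config(path) -> RunConfig:
    """Read and validate a TOML run configuration."""
    with open(path, "rb") as f:
        doc = tomllib.load(f)
    g = doc.get("grid", {})
    grid = GridSpec(
        int(g.get("ndim", 2)),
        tuple(g.get("n", [64, 64])),
        tuple(g.get("extent", [16.0, 16.0])),
    )
    fl = doc.get("fluid", {})
    fluid = FluidParams(
        rho=float(fl.get("rho", 1.0)),
        nu=float(fl.get("nu", 0.03125)),
        dt=float(fl.get("dt", 0.8 / 32768)),
        cfl_limit=float(fl.get("cfl_limit", 0.9)),
        filter_time=fl.get("filter_time", 2.0e-4),
    )
    r = doc.get("run", {})
    return RunConfig(
        grid=grid,
        fluid=fluid,
        ports=_ports_from_list(doc.get("port", [])),
        fixture=r.get("fixture", "ventricle2d"),
        fiber_file=r.get("fiber_file"),
        cycle_period=float(r.get("cycle_period", 0.8)),
        transient=float(r.get("transient", 0.2)),
        n_cycles=int(r.get("n_cycles", 1)),
        field_cadence=int(r.get("field_cadence", 0)),
        checkpoint_cadence=int(r.get("checkpoint_cadence", 0)),
        out=r.get("out", "run.h5"),
        fixture_options=dict(r.get("fixture_options", {})),
    )


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_config(cfg: RunConfig, path):
    """Write a RunConfig back out as TOML (no external writer installed)."""
    lines = ["[grid]"]
    lines.append(f"ndim = {cfg.grid.ndim}")
    lines.append(f"n = {_toml_value(list(cfg.grid.n))}")
    lines.append(f"extent = {_toml_value(list(cfg.grid.extent))}")
    lines += ["", "[fluid]"]
    for k in ("rho", "nu", "dt", "cfl_limit"):
        lines.append(f"{k} = {_toml_value(getattr(cfg.fluid, k))}")
    if cfg.fluid.filter_time is not None:
        lines.append(f"filter_time = {_toml_value(cfg.fluid.filter_time)}")
    lines += ["", "[run]"]
    lines.append(f"fixture = {_toml_value(cfg.fixture)}")
    if cfg.fiber_file:
        lines.append(f"fiber_file = {_toml_value(cfg.fiber_file)}")
    for k in ("cycle_period", "transient", "n_cycles", "field_cadence",
              "checkpoint_cadence"):
        lines.append(f"{k} = {_toml_value(getattr(cfg, k))}")
    lines.append(f"out = {_toml_value(cfg.out)}")
    for p in cfg.ports:
        lines += ["", "[[port]]"]
        lines.append(f"name = {_toml_value(p.name)}")
        lines.append(f"center = {_toml_value(list(p.center))}")
        lines.append(f"radius = {_toml_value(p.radius)}")
        lines.append(f"pressure_mmhg = {_toml_value(p.reservoir_pressure)}")
        lines.append(f"resistance = {_toml_value(p.resistance)}")
        lines.append(f"smoothing_time = {_toml_value(p.smoothing_time)}")
    Path(path).write_text("\n".join(lines) + "\n")
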