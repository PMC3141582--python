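"""Run protocol: transient filling, then N cardiac cycles of the coupled
stepper, with per-step diagnostics, field snapshots at a cadence, and
checkpoint/restart.

Time is step-indexed from t = -transient (so the measured cycles start at
t = 0 exactly at normalized cycle phase 0), and everything downstream of
the configuration is deterministic: identical configurations produce
bitwise-identical containers and CSV series, and a restart from a
checkpoint continues bitwise-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import RunConfig
from .core_fluid import FluidState
from .diagnostics import DiagnosticSeries, chamber_volume, kinetic_energy_slice
from .fixtures import (
    VentricleConfig,
    make_cylinder_wake,
    make_ellipse_membrane,
    make_ellipsoid_membrane_3d,
    make_ventricle_2d,
)
from .immersed_boundary import step_fsi
from .io import RunContainer, load_fiber_csv, series_to_csv

__all__ = ["run", "build_problem", "RunResult"]


@dataclass
class RunResult:
    container_path: Path
    series_path: Path
    series: dict
    state: FluidState
    bstate: object


def build_problem(config: RunConfig):
    """Instantiate (model, bstate, ports) for the configured fixture."""
    grid, fluid = config.grid, config.fluid
    ports = list(config.ports)
    opts = dict(config.fixture_options)
    if config.fixture == "ventricle2d":
        vc_kwargs = dict(
            n=grid.n[0], extent=grid.extent[0], rho=fluid.rho, nu=fluid.nu,
            dt=fluid.dt, T=config.cycle_period,
        )
        vc_kwargs.update(opts)
        model, bstate, fixture_ports, _ = make_ventricle_2d(
            VentricleConfig(**vc_kwargs)
        )
        if not ports:
            ports = fixture_ports
    elif config.fixture == "ellipse":
        model, bstate = make_ellipse_membrane(
            opts.get("a", 3.0), opts.get("b", 2.0),
            int(opts.get("n_points", 256)), opts.get("stiffness", 1.0e4),
            center=tuple(opts.get("center", (grid.extent[0] / 2,) * 2)),
            rest_length_factor=opts.get("rest_length_factor", 0.0),
            grid=grid,
        )
    elif config.fixture == "cylinder":
        wake = make_cylinder_wake(nu=fluid.nu, n=grid.n, extent=grid.extent,
                                  dt=fluid.dt)
        model, bstate = wake["model"], wake["bstate"]
        if not ports:
            ports = wake["ports"]
    elif config.fixture == "ellipsoid3d":
        model, bstate = make_ellipsoid_membrane_3d()
    else:  # "none": user-supplied fiber file
        model, bstate = load_fiber_csv(config.fiber_file)
    if model.cycle_period is None:
        model.cycle_period = config.cycle_period
    return model, bstate, ports


def run(config: RunConfig, resume_from=None, stop_after_steps=None) -> RunResult:
    """Execute the configured run and write the HDF5 container + CSV series.

    ``resume_from`` restarts from the checkpoint of an existing container
    (bitwise-identical continuation).  ``stop_after_steps`` truncates the
    run after that many steps (used for checkpoint/restart testing).
    """
    grid, params = config.grid, config.fluid
    model, bstate, ports = build_problem(config)
    dt = params.dt
    n_total = int(round(config.transient / dt)) + \
        config.n_cycles * config.n_steps_per_cycle
    t0 = -config.transient

    out = Path(config.out)
    series = DiagnosticSeries()
    loop = (model.chamber_loops or {}).get("LV")

    if resume_from is not None:
        container = RunContainer.open(resume_from)
        istart, state, bstate, rates = container.read_checkpoint()
        prev = container.read_series()
        series_arrays = {k: list(v) for k, v in prev.items()}
    else:
        container = RunContainer(out, grid, config.to_json())
        state = FluidState.zeros(grid, t=t0)
        bstate.t = t0
        istart, rates = 0, None
        series_arrays = None

    step_no = istart
    for i in range(istart, n_total):
        state, bstate, info = step_fsi(state, bstate, model, ports, params,
                                       grid, port_rates=rates)
        rates = info.rate_vector
        t = state.t
        t_norm = model.t_norm(t) if t >= 0 else np.nan
        vol = np.nan
        if loop is not None and grid.ndim == 2:
            vol = chamber_volume(bstate.X[loop])
        series.append(
            t, t_norm, info.port_rates,
            ke_max=kinetic_energy_slice(state.u, params.rho, grid, "max"),
            ke_total=kinetic_energy_slice(state.u, params.rho, grid, "total"),
            chamber_volume=vol,
        )
        step_no = i + 1
        if config.field_cadence and step_no % config.field_cadence == 0:
            container.write_fields(step_no, state)
            container.write_fibers(step_no, bstate)
        if config.checkpoint_cadence and step_no % config.checkpoint_cadence == 0:
            container.write_checkpoint(step_no, state, bstate, rates)
        if stop_after_steps is not None and step_no - istart >= stop_after_steps:
            container.write_checkpoint(step_no, state, bstate, rates)
            break

    arrays = series.arrays()
    if series_arrays is not None:  # splice restart continuation
        for k, v in arrays.items():
            series_arrays.setdefault(k, [])
            series_arrays[k] = list(series_arrays[k]) + list(v)
        arrays = {k: np.asarray(v) for k, v in series_arrays.items()}
    container.write_series(arrays)
    container.write_checkpoint(step_no, state, bstate, rates)
    container.close()
    series_path = out.with_suffix(".series.csv")
    series_to_csv(series_path, arrays)
    return RunResult(out, series_path, arrays, state, bstate)
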