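"""Reservoir pressure boundary conditions (RPBC) as localized sources/sinks.

Each vascular opening of the model (SVC, IVC, PV, PA, AO, or user-defined)
is a smeared source blob tied to a fixed external reservoir pressure
through a resistance: the volumetric exchange rate responds to the
difference between the reservoir pressure and the kernel-weighted local
fluid pressure,

    Q_k = (P_reservoir,k - p_local,k) / R_k ,        Q > 0 = inflow.

The rates are realized as a prescribed divergence field; a uniform
compensation field distributes any net residual so the domain integral of
the divergence is exactly zero (periodic solvability).  Local pressures
are sampled with the same regularized kernel shape used for the
immersed-boundary coupling, and are gauge-relative to the domain mean.

Reservoir pressures are configured in mmHg (the clinical convention);
everything else is CGS.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .core_fluid import FluidState, GridSpec
from .immersed_boundary import delta_weight

__all__ = [
    "MMHG_TO_CGS",
    "mmhg_to_cgs",
    "ReservoirPort",
    "SourceField",
    "port_pressure_means",
    "port_flow_rates",
    "build_source_field",
]

#: 1 mmHg in dyn/cm^2 (rho_Hg * g * 0.1 cm in CGS)
MMHG_TO_CGS = 1333.22


def mmhg_to_cgs(p_mmhg):
    """Convert a pressure from mmHg to dyn/cm^2."""
    return np.multiply(p_mmhg, MMHG_TO_CGS)


@dataclass(frozen=True)
class ReservoirPort:
    """One fixed-pressure opening.

    name : label (SVC, IVC, PV, PA, AO, or anything else)
    center : blob center, cm
    radius : support radius of the smeared source blob, cm (>= 2 h)
    reservoir_pressure : external reservoir pressure, mmHg (held constant
        over the cycle by default)
    resistance : port resistance, mmHg s/cm^3
    """

    name: str
    center: tuple[float, ...]
    radius: float
    reservoir_pressure: float
    resistance: float
    #: first-order relaxation time of the port rate toward (P - p)/R, in s.
    #: Represents the inertance of the blood column in the opening and keeps
    #: the pressure-rate feedback loop well-posed; 0 means instantaneous.
    smoothing_time: float = 0.01

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if self.resistance <= 0:
            raise ValueError("port resistance must be positive")
        if self.radius <= 0:
            raise ValueError("port radius must be positive")


@dataclass
class SourceField:
    """Prescribed divergence field (1/s) plus the per-port rates behind it."""

    q: np.ndarray
    port_rates: dict


@functools.lru_cache(maxsize=64)
def _blob(port: ReservoirPort, grid: GridSpec) -> np.ndarray:
    """Normalized smooth blob with unit discrete integral on the grid.

    Product of per-axis 4-point kernels stretched so the support diameter
    equals ``2 * radius``, evaluated with minimum-image periodic offsets,
    then normalized so sum(B) * h^ndim == 1 exactly.
    """
    if port.radius < 2.0 * grid.h:
        raise ValueError(
            f"port '{port.name}' radius {port.radius:.3g} cm is below the "
            f"resolvable minimum 2 h = {2 * grid.h:.3g} cm"
        )
    s = port.radius / 2.0  # kernel support is |r| < 2 in stretched units
    prof = np.ones(grid.n)
    for a in range(grid.ndim):
        x = grid.axis_coords(a)
        L = grid.extent[a]
        d = (x - port.center[a] + L / 2.0) % L - L / 2.0
        w = delta_weight(d / s) / s
        shape = [1] * grid.ndim
        shape[a] = -1
        prof = prof * w.reshape(shape)
    total = float(np.sum(prof)) * grid.cell_volume
    if total <= 0:
        raise ValueError(f"port '{port.name}' blob vanishes on this grid")
    return prof / total


def port_pressure_means(ports, state: FluidState, grid: GridSpec) -> np.ndarray:
    """Blob-weighted mean pressure at each port, dyn/cm^2 (domain-mean gauge)."""
    return np.array(
        [float(np.sum(state.p * _blob(p, grid))) * grid.cell_volume for p in ports]
    )


def port_flow_rates(ports, state: FluidState, grid: GridSpec) -> np.ndarray:
    """Volumetric exchange rate per port: Q = (P_res - p_local) / R.

    Returns cm^3/s in 3-D, cm^2/s (per unit depth) in 2-D; Q > 0 is inflow
    into the domain.
    """
    pbar = port_pressure_means(ports, state, grid)
    pres = mmhg_to_cgs(np.array([p.reservoir_pressure for p in ports]))
    res = mmhg_to_cgs(np.array([p.resistance for p in ports]))  # dyn s/cm^5
    return (pres - pbar) / res


def update_port_rates(
    ports, state: FluidState, grid: GridSpec, prev_rates, dt: float
) -> np.ndarray:
    """Relax port rates toward the instantaneous (P_res - p)/R target.

    ``prev_rates`` is the rate vector carried from the previous stage (None
    starts from zero).  Ports with ``smoothing_time == 0`` jump straight to
    the target.
    """
    target = port_flow_rates(ports, state, grid)
    if prev_rates is None:
        prev_rates = np.zeros(len(ports))
    prev_rates = np.asarray(prev_rates, dtype=float)
    tau = np.array([p.smoothing_time for p in ports])
    alpha = np.where(tau > 0.0, 1.0 - np.exp(-dt / np.maximum(tau, 1e-300)), 1.0)
    return prev_rates + alpha * (target - prev_rates)


def build_source_field(ports, rates, grid: GridSpec) -> SourceField:
    """Assemble the prescribed divergence field q(x) = sum_k Q_k B_k(x).

    Any net residual sum(Q) is removed by a uniform background divergence
    -sum(Q)/V so that the domain integral of q is exactly zero.

    Raises
    ------
    ValueError
        if two port supports overlap.
    """
    ports = list(ports)
    rates = np.asarray(rates, dtype=float)
    for a in range(len(ports)):
        for b in range(a + 1, len(ports)):
            d = _min_image_dist(ports[a].center, ports[b].center, grid)
            if d < ports[a].radius + ports[b].radius:
                raise ValueError(
                    f"ports '{ports[a].name}' and '{ports[b].name}' have "
                    "overlapping supports"
                )
    q = np.zeros(grid.n)
    for port, Q in zip(ports, rates):
        q += Q * _blob(port, grid)
    net = float(np.sum(q)) * grid.cell_volume
    q -= net / grid.volume
    return SourceField(q=q, port_rates={p.name: float(Q) for p, Q in zip(ports, rates)})


def _min_image_dist(c1, c2, grid: GridSpec) -> float:
    d2 = 0.0
    for a in range(grid.ndim):
        L = grid.extent[a]
        d = (c1[a] - c2[a] + L / 2.0) % L - L / 2.0
        d2 += d * d
    return float(np.sqrt(d2))
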