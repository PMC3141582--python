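"""Lagrangian elastic boundaries and their coupling to the fluid grid.

A boundary is a cloud of Lagrangian points joined by Hookean springs whose
stiffness and rest length may be modulated over the cardiac cycle
(activation), plus optional tether (target) points that anchor valve rings,
port rims and wall rest shapes.  Coupling to the Eulerian grid goes both
ways through the same regularized delta function — the standard 4-point
kernel — so force spreading and velocity interpolation are exact adjoints
of one another.

Fiber positions are stored unwrapped; periodic wrapping is applied only
inside the kernel stencil, so spring lengths stay well-defined across the
periodic seam.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core_fluid import (
    FluidParams,
    FluidState,
    GridSpec,
    advect_diffuse_predictor,
    pressure_project,
)

__all__ = [
    "FiberModel",
    "BoundaryState",
    "FSIBlowupError",
    "delta_weight",
    "spread_force",
    "interpolate_velocity",
    "fiber_force",
    "elastic_energy",
    "step_fsi",
    "StepInfo",
]


class FSIBlowupError(RuntimeError):
    """A non-finite value appeared during a coupled step."""


# Activation callable: (t_norm, group) -> (k multiplier, L0 multiplier)
ActivationFn = Callable[[float, str], tuple[float, float]]


@dataclass
class FiberModel:
    """Spring-network description of an elastic immersed boundary.

    Parameters
    ----------
    points : (M, ndim) rest coordinates, cm
    spring_i, spring_j : (S,) endpoint indices of each spring
    spring_k : (S,) reference stiffness, dyn/cm
    spring_L0 : (S,) reference rest length, cm
    spring_group : (S,) activation-group label per spring ("" = passive)
    tether_idx : (K,) indices of anchored points
    tether_target : (K, ndim) fixed anchor coordinates, cm
    tether_k : (K,) tether stiffness, dyn/cm
    ds : (M,) Lagrangian bookkeeping weight per point (dimensionless)
    activation : optional callable (t_norm, group) -> (k_mult, L0_mult)
    cycle_period : cardiac period T in s (t_norm = (t/T) mod 1); None for
        steady problems
    """

    points: np.ndarray
    spring_i: np.ndarray
    spring_j: np.ndarray
    spring_k: np.ndarray
    spring_L0: np.ndarray
    spring_group: np.ndarray = None
    tether_idx: np.ndarray = None
    tether_target: np.ndarray = None
    tether_k: np.ndarray = None
    #: per-tether slack length, cm: the tether exerts no force until the
    #: point is further than this from its target (0 = ordinary tether;
    #: positive models cord-like constraints such as chordae tendineae)
    tether_slack: np.ndarray = None
    ds: np.ndarray = None
    activation: ActivationFn | None = None
    cycle_period: float | None = None
    #: optional named point-index loops outlining chambers (for area series)
    chamber_loops: dict | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        M = self.points.shape[0]
        self.spring_i = np.asarray(self.spring_i, dtype=np.intp)
        self.spring_j = np.asarray(self.spring_j, dtype=np.intp)
        self.spring_k = np.asarray(self.spring_k, dtype=float)
        self.spring_L0 = np.asarray(self.spring_L0, dtype=float)
        S = self.spring_i.shape[0]
        if self.spring_group is None:
            self.spring_group = np.array([""] * S, dtype=object)
        else:
            self.spring_group = np.asarray(self.spring_group, dtype=object)
        if self.tether_idx is None:
            self.tether_idx = np.empty(0, dtype=np.intp)
            self.tether_target = np.empty((0, self.points.shape[1]))
            self.tether_k = np.empty(0)
            self.tether_slack = np.empty(0)
        else:
            self.tether_idx = np.asarray(self.tether_idx, dtype=np.intp)
            self.tether_target = np.asarray(self.tether_target, dtype=float)
            self.tether_k = np.asarray(self.tether_k, dtype=float)
            if self.tether_slack is None:
                self.tether_slack = np.zeros(self.tether_idx.shape[0])
            else:
                self.tether_slack = np.asarray(self.tether_slack, dtype=float)
        if self.ds is None:
            self.ds = np.ones(M)
        else:
            self.ds = np.asarray(self.ds, dtype=float)
        self._validate()

    def _validate(self):
        M = self.points.shape[0]
        if np.any(self.spring_i < 0) or np.any(self.spring_i >= M):
            raise ValueError("spring_i index out of range")
        if np.any(self.spring_j < 0) or np.any(self.spring_j >= M):
            raise ValueError("spring_j index out of range")
        if np.any(self.spring_i == self.spring_j):
            raise ValueError("spring endpoints must differ")
        pairs = set()
        for i, j in zip(self.spring_i, self.spring_j):
            key = (min(i, j), max(i, j))
            if key in pairs:
                raise ValueError(f"duplicate spring {key}")
            pairs.add(key)
        if np.any(self.spring_k < 0) or np.any(self.spring_L0 < 0):
            raise ValueError("spring stiffness and rest length must be >= 0")
        if np.any(self.tether_k < 0):
            raise ValueError("tether stiffness must be >= 0")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_springs(self) -> int:
        return self.spring_i.shape[0]

    def spring_properties(self, t_norm: float) -> tuple[np.ndarray, np.ndarray]:
        """Activated (k, L0) arrays at a normalized cycle time."""
        k = self.spring_k.copy()
        L0 = self.spring_L0.copy()
        if self.activation is not None:
            for g in np.unique(self.spring_group):
                if g == "":
                    continue
                km, lm = self.activation(float(t_norm), str(g))
                sel = self.spring_group == g
                k[sel] *= km
                L0[sel] *= lm
        return k, L0

    def t_norm(self, t: float) -> float:
        if self.cycle_period is None:
            return 0.0
        return float((t / self.cycle_period) % 1.0)


@dataclass
class BoundaryState:
    """Current positions and force densities of the boundary points.

    X : (M, ndim) positions, cm (unwrapped)
    F : (M, ndim) force density, dyn per unit ds
    t : time, s
    """

    X: np.ndarray
    F: np.ndarray = None
    t: float = 0.0

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.F is None:
            self.F = np.zeros_like(self.X)

    def copy(self) -> "BoundaryState":
        return BoundaryState(self.X.copy(), self.F.copy(), self.t)


# ---------------------------------------------------------------------------
# the regularized delta function

def delta_weight(r):
    """Standard 4-point regularized delta kernel phi(r).

    Support |r| < 2, phi >= 0, and the discrete moment identities
    sum_j phi(r - j) = 1 and sum_j (r - j) phi(r - j) = 0 hold for every
    real r, which makes spreading conserve total force and interpolation
    reproduce linear fields exactly.
    """
    r = np.asarray(r, dtype=float)
    a = np.abs(r)
    out = np.zeros_like(a)
    inner = a < 1.0
    outer = (a >= 1.0) & (a < 2.0)
    ai = a[inner]
    out[inner] = (3.0 - 2.0 * ai + np.sqrt(1.0 + 4.0 * ai - 4.0 * ai**2)) / 8.0
    ao = a[outer]
    out[outer] = (5.0 - 2.0 * ao - np.sqrt(-7.0 + 12.0 * ao - 4.0 * ao**2)) / 8.0
    return out if out.ndim else float(out)


def _stencil(X: np.ndarray, grid: GridSpec):
    """Kernel stencil for a batch of points.

    Returns per-axis lists of index arrays (M, 4) wrapped into the periodic
    grid, and weight arrays (M, 4).
    """
    if not np.all(np.isfinite(X)):
        raise FSIBlowupError("non-finite boundary point coordinates")
    h = grid.h
    idx, wgt = [], []
    offs = np.arange(-1, 3)
    for a in range(grid.ndim):
        g = X[:, a] / h - 0.5  # grid-index coordinate of the point
        base = np.floor(g).astype(np.intp)
        nodes = base[:, None] + offs[None, :]
        wgt.append(delta_weight(g[:, None] - nodes))
        idx.append(np.mod(nodes, grid.n[a]))
    return idx, wgt


def spread_force(
    bstate: BoundaryState, model: FiberModel, grid: GridSpec
) -> np.ndarray:
    """Spread boundary force densities onto the grid (Eulerian force field).

    f(x) = sum_m F_m delta_h(x - X_m) ds_m, with delta_h the tensor-product
    4-point kernel scaled by h^-ndim.  Total force is conserved:
    sum_x f h^ndim = sum_m F_m ds_m.
    """
    idx, wgt = _stencil(bstate.X, grid)
    hd = grid.h**grid.ndim
    f = np.zeros((grid.ndim, *grid.n))
    amp = bstate.F * model.ds[:, None] / hd  # (M, ndim)
    if grid.ndim == 2:
        W = wgt[0][:, :, None] * wgt[1][:, None, :]
        flat = (idx[0][:, :, None] * grid.n[1] + idx[1][:, None, :]).ravel()
        for c in range(2):
            f[c] = np.bincount(
                flat, weights=(W * amp[:, c, None, None]).ravel(),
                minlength=grid.ncells,
            ).reshape(grid.n)
    else:
        W = (
            wgt[0][:, :, None, None]
            * wgt[1][:, None, :, None]
            * wgt[2][:, None, None, :]
        )
        flat = (
            (idx[0][:, :, None, None] * grid.n[1] + idx[1][:, None, :, None])
            * grid.n[2]
            + idx[2][:, None, None, :]
        ).ravel()
        for c in range(3):
            f[c] = np.bincount(
                flat, weights=(W * amp[:, c, None, None, None]).ravel(),
                minlength=grid.ncells,
            ).reshape(grid.n)
    return f


def interpolate_velocity(
    u: np.ndarray, bstate: BoundaryState, grid: GridSpec
) -> np.ndarray:
    """Interpolate grid velocity to the boundary points (same kernel).

    U_m = sum_x u(x) delta_h(x - X_m) h^ndim — the exact adjoint of
    :func:`spread_force`.
    """
    idx, wgt = _stencil(bstate.X, grid)
    M = bstate.X.shape[0]
    U = np.empty((M, grid.ndim))
    if grid.ndim == 2:
        W = wgt[0][:, :, None] * wgt[1][:, None, :]
        vals_idx = (idx[0][:, :, None], idx[1][:, None, :])
        for c in range(2):
            U[:, c] = np.sum(u[c][vals_idx] * W, axis=(1, 2))
    else:
        W = (
            wgt[0][:, :, None, None]
            * wgt[1][:, None, :, None]
            * wgt[2][:, None, None, :]
        )
        vals_idx = (
            idx[0][:, :, None, None],
            idx[1][:, None, :, None],
            idx[2][:, None, None, :],
        )
        for c in range(3):
            U[:, c] = np.sum(u[c][vals_idx] * W, axis=(1, 2, 3))
    return U


# ---------------------------------------------------------------------------
# fiber constitutive law

def fiber_force(
    bstate: BoundaryState, model: FiberModel, t_norm: float
) -> np.ndarray:
    """Boundary force densities from the activated spring network.

    Each spring (i, j) carries tension T = k(t) (|Xj - Xi| - L0(t)) along
    the connector; tethered points additionally feel
    k_teth (X_target - X).  The per-point force is divided by ds to give a
    force density.  Springs with coincident endpoints contribute zero (the
    defined limit of the direction vector).
    """
    if not (0.0 <= t_norm <= 1.0):
        raise ValueError("t_norm must lie in [0, 1]")
    X = bstate.X
    M, nd = X.shape
    force = np.zeros((M, nd))
    if model.n_springs:
        k, L0 = model.spring_properties(t_norm)
        d = X[model.spring_j] - X[model.spring_i]
        length = np.linalg.norm(d, axis=1)
        ok = length > 0.0
        tension = np.where(ok, k * (length - L0), 0.0)
        unit = np.zeros_like(d)
        unit[ok] = d[ok] / length[ok, None]
        fvec = tension[:, None] * unit  # pulls i toward j when stretched
        np.add.at(force, model.spring_i, fvec)
        np.add.at(force, model.spring_j, -fvec)
    if model.tether_idx.size:
        d = model.tether_target - X[model.tether_idx]
        if np.any(model.tether_slack > 0.0):
            dist = np.linalg.norm(d, axis=1)
            engaged = np.maximum(dist - model.tether_slack, 0.0)
            scale = np.where(dist > 0.0, engaged / np.maximum(dist, 1e-300), 0.0)
            pull = model.tether_k[:, None] * scale[:, None] * d
        else:
            pull = model.tether_k[:, None] * d
        np.add.at(force, model.tether_idx, pull)
    return force / model.ds[:, None]


def elastic_energy(
    bstate: BoundaryState, model: FiberModel, t_norm: float = 0.0
) -> float:
    """Total spring + tether potential energy, erg (per unit depth in 2-D)."""
    X = bstate.X
    e = 0.0
    if model.n_springs:
        k, L0 = model.spring_properties(t_norm)
        length = np.linalg.norm(X[model.spring_j] - X[model.spring_i], axis=1)
        e += float(np.sum(0.5 * k * (length - L0) ** 2))
    if model.tether_idx.size:
        d = model.tether_target - X[model.tether_idx]
        ext = np.maximum(np.linalg.norm(d, axis=1) - model.tether_slack, 0.0)
        e += float(np.sum(0.5 * model.tether_k * ext**2))
    return e


# ---------------------------------------------------------------------------
# the coupled time step

@dataclass
class StepInfo:
    """Per-step diagnostics emitted by :func:`step_fsi`.

    ``rate_vector`` is the relaxed port-rate state to feed into the next
    call; ``port_rates`` is the same keyed by port name.
    """

    courant: float = 0.0
    port_rates: dict = field(default_factory=dict)
    rate_vector: np.ndarray | None = None
    max_div_err: float = 0.0


def _source_field(ports, state, grid, prev_rates, dt):
    """Port divergence field and relaxed rates for the current pressure;
    lazy import to keep the module dependency one-way."""
    from .sources import build_source_field, update_port_rates

    if not ports:
        return np.zeros(grid.n), None
    rates = update_port_rates(ports, state, grid, prev_rates, dt)
    sf = build_source_field(ports, rates, grid)
    return sf.q, rates


def step_fsi(
    state: FluidState,
    bstate: BoundaryState,
    model: FiberModel,
    ports,
    params: FluidParams,
    grid: GridSpec,
    port_rates: np.ndarray | None = None,
) -> tuple[FluidState, BoundaryState, StepInfo]:
    """Advance fluid and boundary together from t to t + dt.

    Two-stage time-centered (Crank-Nicolson) scheme:

    a. evaluate fiber forces at X^n, spread them, take a half step of the
       fluid to n+1/2, interpolate and move the fibers to X^(n+1/2);
    b. evaluate forces at X^(n+1/2), spread, take the full step n -> n+1
       with the advective term evaluated at the midpoint velocity, then move
       the fibers with the time-centered velocity (u^n + u^(n+1))/2
       interpolated at X^(n+1/2).

    Port source strengths are recomputed at each stage from the current
    pressure field, relaxed over each port's smoothing time;
    ``port_rates`` carries the rate vector from the previous step (pass
    ``info.rate_vector`` back in to continue a run).
    """
    dt = params.dt
    t = state.t

    # --- stage a: half step
    tn_a = model.t_norm(t)
    F_n = fiber_force(bstate, model, tn_a)
    bstate_n = BoundaryState(bstate.X, F_n, t)
    f_grid = spread_force(bstate_n, model, grid)
    q_a, rates_a = _source_field(ports, state, grid, port_rates, dt / 2)

    ustar = advect_diffuse_predictor(state, f_grid, params, grid, dt / 2)
    u_half, p_half = pressure_project(ustar, q_a, params, grid, dt / 2)
    half_state = FluidState(u_half, p_half, t + dt / 2)

    U_n = interpolate_velocity(u_half, bstate_n, grid)
    X_half = bstate.X + (dt / 2) * U_n
    bstate_half = BoundaryState(X_half, t=t + dt / 2)

    # --- stage b: full step with time-centered forces
    tn_b = model.t_norm(t + dt / 2)
    F_half = fiber_force(bstate_half, model, tn_b)
    bstate_half.F = F_half
    f_grid2 = spread_force(bstate_half, model, grid)
    q_b, rates_b = _source_field(ports, half_state, grid, rates_a, dt / 2)

    ustar2 = advect_diffuse_predictor(
        state, f_grid2, params, grid, dt, advect_state=half_state
    )
    u_new, p_new = pressure_project(ustar2, q_b, params, grid, dt)

    centered = FluidState(0.5 * (state.u + u_new), p_new, t + dt / 2)
    U_half = interpolate_velocity(centered.u, bstate_half, grid)
    X_new = bstate.X + dt * U_half

    if not (np.all(np.isfinite(u_new)) and np.all(np.isfinite(X_new))):
        raise FSIBlowupError(f"non-finite field at t = {t + dt:.6e} s")

    new_state = FluidState(u_new, p_new, t + dt)
    new_bstate = BoundaryState(X_new, F_half, t + dt)
    from .core_fluid import courant_number, divergence

    info = StepInfo(
        courant=courant_number(u_new, dt, grid),
        port_rates=(
            {} if rates_b is None
            else {p.name: float(q) for p, q in zip(ports, rates_b)}
        ),
        rate_vector=rates_b,
        max_div_err=float(np.max(np.abs(divergence(u_new, grid) - q_b))),
    )
    return new_state, new_bstate, info
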