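"""Synthetic geometries and activation schedules for chamber-flow studies.

Three families of test inputs, all deterministic functions of their
configuration (no randomness anywhere):

* a closed elastic membrane ring (ellipse), the canonical verification
  geometry for diffuse-interface boundary coupling (area conservation,
  Laplace pressure jump);
* a tethered rigid-cylinder ring in a port-driven stream, for the classic
  vortex-street validation (periodic wake at Re ~ 100, steady at Re ~ 20);
* a simplified 2-D two-chamber "atrium + conical ventricle" with mitral
  and aortic valve flaps, a pulmonary-vein port (15 mmHg reservoir), an
  aortic port (80 mmHg), and an E/A/S activation schedule, standing in for
  the anatomical heart at desk scale.

Chamber walls are anchored to their diastolic rest shape by weak tethers
(the anatomical heart is held by its fiber architecture, which is out of
scope here); valve rings, port rims and conduit walls get stiff tethers.
Contraction and relaxation are driven by time-varying spring stiffness and
rest length, so diastolic filling is elastic recoil and systolic ejection
is active shortening.  The valve flaps are free fiber chains hinged at
tethered endpoints; like the full anatomical model, they cannot form a
perfectly sealed valve, so a small regurgitant flow is expected and
documented rather than suppressed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_fluid import FluidParams, GridSpec
from .immersed_boundary import BoundaryState, FiberModel
from .sources import ReservoirPort

__all__ = [
    "ActivationSchedule",
    "activation_value",
    "make_activation",
    "make_ellipse_membrane",
    "make_cylinder_ring",
    "make_cylinder_wake",
    "make_ventricle_2d",
    "make_ellipsoid_membrane_3d",
    "VentricleConfig",
    "UnderResolvedBoundaryWarning",
]


class UnderResolvedBoundaryWarning(UserWarning):
    """Fiber spacing too coarse relative to the grid: leakage risk."""


# ---------------------------------------------------------------------------
# activation

@dataclass(frozen=True)
class ActivationSchedule:
    """Phase timings and modulation depths over the normalized cycle.

    The cycle convention: diastole spans 0-0.75 T (containing the E- and
    A-waves) and systole spans 0.75-1.0 T (the S-wave).  Within diastole the
    E-wave is the early, recoil-driven filling window and the A-wave is a
    brief atrial-contraction pulse centered at ``a_wave_center``.

    ``depths`` maps a fiber group name to its peak (k multiplier, L0
    multiplier) at full activation; groups not listed stay at (1, 1).
    All transitions are C^1 piecewise-cosine ramps, periodic in t_norm.
    """

    T: float = 0.8
    diastole_span: tuple[float, float] = (0.0, 0.75)
    e_wave_span: tuple[float, float] = (0.0, 0.25)
    a_wave_center: float = 0.5
    a_wave_width: float = 0.24
    systole_span: tuple[float, float] = (0.75, 1.0)
    ramp: float = 0.06
    #: where in the cycle ventricular relaxation begins (isovolumic
    #: relaxation starts just before end-systole) and how long the cosine
    #: release ramp lasts
    release_start: float = 1.0
    release: float = 0.12
    depths: dict = field(
        default_factory=lambda: {
            "ventricle": (2.0, 0.35),
            "atrium": (1.5, 0.55),
        }
    )

    def __post_init__(self):
        d0, d1 = self.diastole_span
        s0, s1 = self.systole_span
        for a, b in (self.diastole_span, self.e_wave_span, self.systole_span):
            if not (0.0 <= a < b <= 1.0):
                raise ValueError("phase spans must be ordered within [0, 1]")
        if not (d1 <= s0):
            raise ValueError("diastole and systole must not overlap")
        if not (d0 <= self.a_wave_center <= d1):
            raise ValueError("a_wave_center must fall inside diastole")


def _cos_ramp(x: float) -> float:
    """Smooth 0 -> 1 ramp on [0, 1] with zero slope at both ends."""
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    return 0.5 * (1.0 - math.cos(math.pi * x))


def _systolic_envelope(schedule: ActivationSchedule, t: float) -> float:
    s0, _ = schedule.systole_span
    w = schedule.ramp
    rs = schedule.release_start
    r = schedule.release
    d = (t - rs) % 1.0
    if d < r:  # release ramp, possibly wrapping the cycle seam
        return 1.0 - _cos_ramp(d / r)
    if s0 <= t < rs:
        return _cos_ramp((t - s0) / w)
    return 0.0


def _atrial_envelope(schedule: ActivationSchedule, t: float) -> float:
    c = schedule.a_wave_center
    hw = schedule.a_wave_width / 2.0
    d = abs(t - c)
    d = min(d, 1.0 - d)  # periodic distance
    if d >= hw:
        return 0.0
    return math.cos(math.pi * d / (2.0 * hw)) ** 2


def activation_value(
    schedule: ActivationSchedule, t_norm: float, group: str
) -> tuple[float, float]:
    """(k multiplier, L0 multiplier) for one fiber group at t_norm."""
    if not (0.0 <= t_norm <= 1.0):
        raise ValueError("t_norm must lie in [0, 1]")
    if group not in schedule.depths:
        return (1.0, 1.0)
    if group == "atrium":
        env = _atrial_envelope(schedule, t_norm)
    else:
        env = _systolic_envelope(schedule, t_norm)
    k_peak, L0_peak = schedule.depths[group]
    return (1.0 + (k_peak - 1.0) * env, 1.0 + (L0_peak - 1.0) * env)


def make_activation(schedule: ActivationSchedule):
    """Bind a schedule into the (t_norm, group) callable FiberModel expects."""

    def fn(t_norm: float, group: str) -> tuple[float, float]:
        return activation_value(schedule, t_norm, group)

    return fn


# ---------------------------------------------------------------------------
# chain-building helpers

def _chain_springs(offset, npts, k, L0, group="", closed=False):
    """NN spring arrays for a chain of npts points starting at point index
    ``offset``; L0 may be scalar or per-spring."""
    i = np.arange(npts - 1) + offset
    j = i + 1
    if closed:
        i = np.append(i, offset + npts - 1)
        j = np.append(j, offset)
    ns = len(i)
    return (
        i,
        j,
        np.full(ns, float(k)),
        np.broadcast_to(np.asarray(L0, dtype=float), (ns,)).copy(),
        np.array([group] * ns, dtype=object),
    )


class _Builder:
    """Accumulates points, springs and tethers for a composite fiber model."""

    def __init__(self, ndim=2):
        self.ndim = ndim
        self.pts = []
        self.si, self.sj, self.sk, self.sL, self.sg = [], [], [], [], []
        self.ti, self.tt, self.tk, self.ts = [], [], [], []

    def add_chain(self, pts, k, group="", closed=False, L0=None,
                  tether_k=None, nnn_k=None):
        """Add a polyline chain with NN springs (natural rest lengths by
        default), optional next-nearest springs (bending stiffness) and
        optional uniform tethering to the rest positions."""
        pts = np.asarray(pts, dtype=float)
        off = len(self.pts)
        n = pts.shape[0]
        self.pts.extend(pts)
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]) if closed
                                     else pts, axis=0), axis=1)
        if L0 is None:
            L0_arr = seg
        else:
            L0_arr = np.broadcast_to(np.asarray(L0, float), seg.shape).copy()
        i, j, kk, ll, gg = _chain_springs(off, n, k, L0_arr, group, closed)
        self._push(i, j, kk, ll, gg)
        if nnn_k:
            i2 = np.arange(n - 2) + off
            j2 = i2 + 2
            rest2 = np.linalg.norm(pts[2:] - pts[:-2], axis=1)
            self._push(i2, j2, np.full(n - 2, float(nnn_k)), rest2,
                       np.array([group] * (n - 2), dtype=object))
        if tether_k is not None:
            tk = np.broadcast_to(np.asarray(tether_k, float), (n,))
            sel = tk > 0
            self.ti.extend((np.arange(n) + off)[sel])
            self.tt.extend(pts[sel])
            self.tk.extend(tk[sel])
            self.ts.extend([0.0] * int(sel.sum()))
        return off, n

    def tether(self, idx, target, k, slack=0.0):
        self.ti.append(idx)
        self.tt.append(np.asarray(target, float))
        self.tk.append(float(k))
        self.ts.append(float(slack))

    def _push(self, i, j, k, L0, g):
        self.si.extend(i)
        self.sj.extend(j)
        self.sk.extend(k)
        self.sL.extend(L0)
        self.sg.extend(g)

    def build(self, activation=None, cycle_period=None):
        model = FiberModel(
            points=np.array(self.pts),
            spring_i=np.array(self.si, dtype=np.intp),
            spring_j=np.array(self.sj, dtype=np.intp),
            spring_k=np.array(self.sk),
            spring_L0=np.array(self.sL),
            spring_group=np.array(self.sg, dtype=object),
            tether_idx=np.array(self.ti, dtype=np.intp) if self.ti else None,
            tether_target=np.array(self.tt) if self.ti else None,
            tether_k=np.array(self.tk) if self.ti else None,
            tether_slack=np.array(self.ts) if self.ti else None,
            activation=activation,
            cycle_period=cycle_period,
        )
        return model, BoundaryState(model.points.copy())


def check_spacing(points: np.ndarray, grid: GridSpec, closed=False,
                  label="boundary"):
    """Warn when fiber spacing exceeds h/2 (the anti-leakage rule)."""
    pts = np.vstack([points, points[:1]]) if closed else points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if seg.size and float(seg.max()) > grid.h / 2.0 + 1e-12:
        warnings.warn(
            f"{label}: fiber spacing {seg.max():.3g} cm exceeds h/2 = "
            f"{grid.h / 2:.3g} cm; the membrane may leak",
            UnderResolvedBoundaryWarning,
        )


# ---------------------------------------------------------------------------
# elementary fixtures

def _ellipse_points(a, b, n_points, center):
    th = 2.0 * np.pi * np.arange(n_points) / n_points
    return np.column_stack([center[0] + a * np.cos(th),
                            center[1] + b * np.sin(th)])


def make_ellipse_membrane(
    a: float,
    b: float,
    n_points: int,
    stiffness: float,
    center=(0.0, 0.0),
    rest_length_factor: float = 1.0,
    grid: GridSpec | None = None,
) -> tuple[FiberModel, BoundaryState]:
    """Closed elastic ring along an ellipse (semi-axes a, b in cm).

    ``rest_length_factor`` scales the spring rest length relative to the
    initial segment length: 1.0 gives an equilibrium configuration, 0.0 a
    pure tension ring that relaxes toward a circle while the enclosed
    (incompressible) area is conserved.
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    pts = _ellipse_points(a, b, n_points, center)
    if grid is not None:
        check_spacing(pts, grid, closed=True, label="ellipse membrane")
    bld = _Builder()
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    bld.add_chain(pts, stiffness, closed=True, L0=rest_length_factor * seg)
    return bld.build()


def make_cylinder_ring(
    center,
    radius: float,
    n_points: int,
    tether_stiffness: float,
    grid: GridSpec | None = None,
    ring_stiffness: float | None = None,
) -> tuple[FiberModel, BoundaryState]:
    """Rigid-cylinder stand-in: a ring of points stiffly tethered in place."""
    if grid is not None and radius < 4.0 * grid.h:
        raise ValueError(f"cylinder radius must be >= 4 h = {4 * grid.h:.3g} cm")
    pts = _ellipse_points(radius, radius, n_points, center)
    if grid is not None:
        check_spacing(pts, grid, closed=True, label="cylinder ring")
    bld = _Builder()
    if ring_stiffness is None:
        ring_stiffness = tether_stiffness / 4.0
    bld.add_chain(pts, ring_stiffness, closed=True, tether_k=tether_stiffness)
    return bld.build()


def make_cylinder_wake(nu: float = 0.16, n=(128, 32), extent=(32.0, 8.0),
                       dt: float = 8.0e-4, tether_stiffness: float = 2.0e4):
    """Cylinder in a stream driven by two balanced reservoir ports.

    A high-pressure source blob upstream and a matching low-pressure sink
    downstream push a stream of a few cm/s past a tethered circular
    cylinder of diameter 2 cm; the cylinder center is offset 0.1 cm from
    the source-sink axis to break the initial symmetry.  The Reynolds
    number is selected through the viscosity: nu = 0.16 cm^2/s gives
    Re ~ 100 (periodic vortex street), nu = 0.8 gives Re ~ 20 (steady
    wake), at the same driving.

    Returns a dict with grid, params, model, bstate, ports, the cylinder
    spec and a wake probe location.
    """
    grid = GridSpec(2, tuple(n), tuple(extent))
    params = FluidParams(rho=1.0, nu=nu, dt=dt, cfl_limit=0.9)
    radius = 1.0
    center = (9.0, extent[1] / 2.0 + 0.1)
    npts = max(int(np.ceil(2 * np.pi * radius / (grid.h / 2))), 16)
    model, bstate = make_cylinder_ring(center, radius, npts,
                                       tether_stiffness, grid=grid)
    # source and sink sit half a domain apart, so the direct path (through
    # the cylinder) and the periodic wrap path have equal hydraulic length
    # and each carries half the exchanged flux; the cylinder stands a few
    # diameters downstream of the source with ~4 diameters of open wake
    # before the sink
    dp = 5.0  # mmHg; with R = 0.05 mmHg s/cm^3 this drives O(100) cm^2/s
    ports = [
        ReservoirPort("inlet", (4.0, extent[1] / 2.0), 1.6, +dp, 0.05),
        ReservoirPort("outlet", (20.0, extent[1] / 2.0), 1.6, -dp, 0.05),
    ]
    return {
        "grid": grid,
        "params": params,
        "model": model,
        "bstate": bstate,
        "ports": ports,
        "cylinder_center": center,
        "cylinder_radius": radius,
        "probe": (13.0, extent[1] / 2.0),
        "upstream_probe": (6.5, extent[1] / 2.0),
    }


def cylinder_wake_initial_state(wake: dict):
    """Initial fluid state for the wake study: a deterministic transverse
    velocity pulse in the near wake seeds the antisymmetric (shedding) mode,
    shortening the transient before the wake either saturates into a
    periodic street (supercritical Re) or decays (subcritical)."""
    from .core_fluid import FluidState

    grid = wake["grid"]
    state = FluidState.zeros(grid)
    cx, cy = wake["cylinder_center"]
    X, Y = grid.meshgrid()
    x0 = cx + 2.5 * wake["cylinder_radius"]
    state.u[1] += 3.0 * np.exp(-(((X - x0) ** 2) + (Y - cy + 0.1) ** 2) / 2.0)
    return state


# ---------------------------------------------------------------------------
# the 2-D two-chamber ventricle

@dataclass(frozen=True)
class VentricleConfig:
    """Geometry, stiffness and port parameters of the 2-D heart fixture.

    All lengths in cm, stiffnesses in dyn/cm, pressures in mmHg,
    resistances in mmHg s/cm^3.  The defaults are sized for a 16 x 16 cm
    periodic box at 64^2 cells and are chosen so the ventricle fills over
    roughly the first half of diastole and ejects during the 0.25 T
    systole.
    """

    n: int = 64
    extent: float = 16.0
    rho: float = 1.0
    nu: float = 0.03125
    dt: float = 0.8 / 32768
    T: float = 0.8

    # ventricle chamber: ellipse arc, apex down
    v_center: tuple[float, float] = (8.0, 8.8)
    v_rx: float = 2.3
    v_ry: float = 4.5
    roof_y: float = 8.8
    # mitral opening in the roof
    mitral_left: float = 6.6
    mitral_right: float = 8.0
    # aortic conduit (dead-end channel holding the AO port)
    ao_left: float = 8.9
    ao_right: float = 10.3
    ao_top: float = 11.0
    # aortic valve mouth (throat) within the conduit base
    ao_mouth_left: float = 9.2
    ao_mouth_right: float = 10.0
    #: second fiber curtain offset for pressure-holding walls, cm; a double
    #: layer strongly reduces the porous leakage of the diffuse interface
    wall_layer_offset: float = 0.125
    # atrium: ellipse arc over the mitral opening
    la_center: tuple[float, float] = (7.3, 10.2)
    la_rx: float = 1.2
    la_ry: float = 1.7

    flap_len: float = 1.1
    flap_pts: int = 18
    #: how far each leaflet tip reaches past the opening midline at rest;
    #: the crossed (X) rest configuration seals under reverse pressure and
    #: swings open under forward pressure
    flap_overlap: float = 0.35
    mitral_overlap: float = 0.45

    # fiber extensional rigidities, dyn (tension = K * strain); the
    # per-spring stiffness k = K / segment-length follows from the point
    # spacing, so the wall's load capacity is independent of discretization
    k_ventricle: float = 2.0e5
    k_atrium: float = 8.0e4
    k_conduit: float = 8.0e4
    k_flap: float = 4.0e3
    k_flap_bend: float = 6.0e2
    k_ao_flap: float = 1.2e4
    k_ao_flap_bend: float = 1.0e4
    # tether stiffness per cm of fiber (dyn/cm per cm); per-point values
    # scale with the local spacing
    teth_wall: float = 1.6e5
    teth_conduit: float = 2.4e6
    teth_rim: float = 8.0e5
    teth_flap_hinge: float = 8.0e5
    teth_flap_root: float = 4.0e4
    teth_ao_flap_root: float = 2.0e5
    #: chordae-tendineae stand-in: each mitral leaflet tip is tethered to a
    #: papillary anchor below the valve plane, preventing systolic prolapse
    #: into the atrium while leaving the diastolic opening free
    k_chordae: float = 4.0e5

    # ports
    pv_pressure: float = 15.0
    pv_resistance: float = 1.2
    ao_pressure: float = 80.0
    ao_resistance: float = 1.5
    port_radius: float = 0.5

    # activation depths
    v_k_peak: float = 1.8
    v_L0_peak: float = 0.25
    a_k_peak: float = 2.5
    a_L0_peak: float = 0.22

    def grid(self) -> GridSpec:
        return GridSpec.cube(2, self.n, self.extent)

    def fluid(self) -> FluidParams:
        return FluidParams(rho=self.rho, nu=self.nu, dt=self.dt)

    def schedule(self) -> ActivationSchedule:
        return ActivationSchedule(
            T=self.T,
            depths={
                "ventricle": (self.v_k_peak, self.v_L0_peak),
                "atrium": (self.a_k_peak, self.a_L0_peak),
            },
        )


def _arc_points(cx, cy, rx, ry, th0, th1, spacing, phase=0.0):
    """Points along an ellipse arc with near-uniform arclength spacing.

    ``phase`` shifts the interior points by a fraction of the spacing, so
    stacked wall layers can be tangentially staggered against leakage.
    """
    tfine = np.linspace(th0, th1, 2048)
    x = cx + rx * np.cos(tfine)
    y = cy + ry * np.sin(tfine)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
    npts = max(int(np.ceil(s[-1] / spacing)) + 1, 2)
    si = np.clip(np.linspace(0.0, s[-1], npts) + phase * spacing, 0.0, s[-1])
    return np.column_stack([np.interp(si, s, x), np.interp(si, s, y)])


def _line_points(p0, p1, spacing):
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    L = float(np.linalg.norm(p1 - p0))
    npts = max(int(np.ceil(L / spacing)) + 1, 2)
    t = np.linspace(0.0, 1.0, npts)[:, None]
    return p0 + t * (p1 - p0)


def make_ventricle_2d(
    config: VentricleConfig | None = None,
) -> tuple[FiberModel, BoundaryState, list[ReservoirPort], ActivationSchedule]:
    """Build the 2-D two-chamber heart fixture.

    Returns (model, bstate, ports, schedule).  The interior is one
    connected region: PV port -> atrium -> mitral opening (two flaps) ->
    ventricle -> aortic conduit mouth (two flaps) -> dead-end conduit
    holding the AO port.  Exchange with the reservoirs happens through the
    port source blobs, so the conduit needs no outlet to the far field.

    The ventricular wall springs carry the "ventricle" activation group
    (systolic shortening), the atrial wall the "atrium" group (A-wave
    pulse); everything else is passive.
    """
    cfg = config or VentricleConfig()
    grid = cfg.grid()
    h = grid.h
    spacing = h / 4.0  # denser than the h/2 anti-leakage bound: the chambers
    # hold tens of mmHg across a fiber curtain for most of the cycle
    sched = cfg.schedule()

    # --- sanity of geometry vs ports
    for name, x, y in (("PV", *cfg.la_center), ("AO", 0.5 * (cfg.ao_left + cfg.ao_right), 0.5 * (cfg.roof_y + cfg.ao_top))):
        if not (0 < x < cfg.extent and 0 < y < cfg.extent):
            raise ValueError(f"{name} port outside the domain")

    bld = _Builder()
    cx, cy = cfg.v_center
    kv = cfg.k_ventricle / spacing
    ka = cfg.k_atrium / spacing
    kc = cfg.k_conduit / spacing
    fseg = cfg.flap_len / (cfg.flap_pts - 1)
    kf, kfb = cfg.k_flap / fseg, cfg.k_flap_bend / fseg
    kaf, kafb = cfg.k_ao_flap / fseg, cfg.k_ao_flap_bend / fseg
    tw = cfg.teth_wall * spacing
    tc = cfg.teth_conduit * spacing

    dl = cfg.wall_layer_offset

    # ventricular free wall: ellipse arc from roof left to roof right, apex
    # down; two concentric curtains against porous leakage
    thL = math.pi  # (cx - rx, cy)
    thR = 2.0 * math.pi
    vw = _arc_points(cx, cy, cfg.v_rx, cfg.v_ry, thL, thR, spacing)
    off_lv, n_lv = bld.add_chain(vw, kv, group="ventricle", tether_k=tw)
    for m, ph in ((1, 0.5), (2, 0.25)):
        vwm = _arc_points(cx, cy, cfg.v_rx + m * dl, cfg.v_ry + m * dl,
                          thL, thR, spacing, phase=ph)
        bld.add_chain(vwm, kv, group="ventricle", tether_k=tw)

    # roof segments (passive, stiffly held), double-layered
    for x0, x1 in ((cx - cfg.v_rx, cfg.mitral_left),
                   (cfg.mitral_right, cfg.ao_mouth_left),
                   (cfg.ao_mouth_right, cfg.ao_right)):
        for dy in (0.0, dl):
            bld.add_chain(_line_points((x0, cfg.roof_y + dy),
                                       (x1, cfg.roof_y + dy), spacing),
                          kc, tether_k=tc)

    # aortic conduit: two side walls and a closed top, double-layered outward
    for seg in (
        _line_points((cfg.ao_left, cfg.roof_y), (cfg.ao_left, cfg.ao_top), spacing),
        _line_points((cfg.ao_left - dl, cfg.roof_y), (cfg.ao_left - dl, cfg.ao_top), spacing),
        _line_points((cfg.ao_right, cfg.roof_y), (cfg.ao_right, cfg.ao_top), spacing),
        _line_points((cfg.ao_right + dl, cfg.roof_y), (cfg.ao_right + dl, cfg.ao_top), spacing),
        _line_points((cfg.ao_left - dl, cfg.ao_top), (cfg.ao_right + dl, cfg.ao_top), spacing),
        _line_points((cfg.ao_left - dl, cfg.ao_top + dl), (cfg.ao_right + dl, cfg.ao_top + dl), spacing),
    ):
        bld.add_chain(seg, kc, tether_k=tc)

    # atrium: ellipse arc over the mitral opening, rim to rim the long way
    lcx, lcy = cfg.la_center
    thA0 = math.atan2(cfg.roof_y - lcy, (cfg.mitral_left - lcx))
    thA1 = math.atan2(cfg.roof_y - lcy, (cfg.mitral_right - lcx))
    # angles on the ellipse parameterization
    def _ell_angle(x, y):
        return math.atan2((y - lcy) / cfg.la_ry, (x - lcx) / cfg.la_rx)

    a0 = _ell_angle(cfg.mitral_left, cfg.roof_y)
    a1 = _ell_angle(cfg.mitral_right, cfg.roof_y)
    if a0 < a1:
        a0 += 2.0 * math.pi  # go over the top from left rim to right rim
    la = _arc_points(lcx, lcy, cfg.la_rx, cfg.la_ry, a1, a0, spacing)
    bld.add_chain(la, ka, group="atrium", tether_k=tw)
    la2 = _arc_points(lcx, lcy, cfg.la_rx + dl, cfg.la_ry + dl, a1, a0, spacing)
    bld.add_chain(la2, ka, group="atrium", tether_k=tw)

    # valve flaps: free chains hinged at stiffly tethered rim points.
    # Mitral flaps hang down-inward (rest shape ~closed); forward (E-wave)
    # flow pushes them apart, ventricular pressure presses them shut.
    gap = cfg.mitral_right - cfg.mitral_left
    mid = 0.5 * (cfg.mitral_left + cfg.mitral_right)
    reach = gap / 2 + cfg.mitral_overlap
    drop = math.sqrt(max(cfg.flap_len**2 - reach**2, 0.01))
    for x0, xtip, side in ((cfg.mitral_left, mid + cfg.mitral_overlap, -1),
                           (cfg.mitral_right, mid - cfg.mitral_overlap, +1)):
        pts = _line_points((x0, cfg.roof_y), (xtip, cfg.roof_y - drop),
                           cfg.flap_len / (cfg.flap_pts - 1))
        off, npts_f = bld.add_chain(pts, kf, nnn_k=kfb)
        bld.tether(off, pts[0], cfg.teth_flap_hinge)
        bld.tether(off + 1, pts[1], cfg.teth_flap_root)
        bld.tether(off + 2, pts[2], cfg.teth_flap_root / 4.0)
        # chordae: slack cords from the distal leaflet to papillary anchors
        # below the valve plane; they engage only when the leaflet is pushed
        # back toward the atrium, preventing prolapse without hindering the
        # diastolic opening
        if cfg.k_chordae > 0:
            for pidx, lateral in ((npts_f - 1, 0.3), (npts_f - 4, 0.45),
                                  (npts_f - 7, 0.6)):
                anchor = np.array([mid + side * lateral, cfg.roof_y - 1.9])
                rest_d = float(np.linalg.norm(pts[pidx] - anchor))
                bld.tether(off + pidx, anchor, cfg.k_chordae,
                           slack=rest_d)

    # aortic flaps point up-inward; systolic pressure opens them into the
    # conduit, reservoir back-pressure presses them closed.
    agap = cfg.ao_mouth_right - cfg.ao_mouth_left
    amid = 0.5 * (cfg.ao_mouth_left + cfg.ao_mouth_right)
    areach = agap / 2 + cfg.flap_overlap
    arise = math.sqrt(max(cfg.flap_len**2 - areach**2, 0.01))
    for x0, xtip, side in ((cfg.ao_mouth_left, amid + cfg.flap_overlap, +1),
                           (cfg.ao_mouth_right, amid - cfg.flap_overlap, -1)):
        pts = _line_points((x0, cfg.roof_y), (xtip, cfg.roof_y + arise),
                           cfg.flap_len / (cfg.flap_pts - 1))
        off, npts_f = bld.add_chain(pts, kaf, nnn_k=kafb)
        bld.tether(off, pts[0], cfg.teth_flap_hinge)
        bld.tether(off + 1, pts[1], cfg.teth_ao_flap_root)
        bld.tether(off + 2, pts[2], cfg.teth_ao_flap_root / 4.0)
        # retaining cords into the conduit: slack while the valve opens
        # upward, taut against reverse (diastolic) blow-through
        if cfg.k_chordae > 0:
            for pidx, lateral in ((npts_f - 1, 0.2), (npts_f - 4, 0.35)):
                anchor = np.array([amid + side * lateral,
                                   cfg.roof_y + arise + 0.6])
                rest_d = float(np.linalg.norm(pts[pidx] - anchor))
                bld.tether(off + pidx, anchor, cfg.k_chordae, slack=rest_d)

    model, bstate = bld.build(activation=make_activation(sched),
                              cycle_period=cfg.T)
    model.chamber_loops = {"LV": np.arange(off_lv, off_lv + n_lv)}
    check_spacing(vw, grid, label="ventricular wall")
    check_spacing(la, grid, label="atrial wall")

    conduit_mid = 0.5 * (cfg.ao_left + cfg.ao_right)
    ports = [
        ReservoirPort("PV", (lcx, lcy + 0.6), cfg.port_radius,
                      cfg.pv_pressure, cfg.pv_resistance),
        ReservoirPort("AO", (conduit_mid, cfg.ao_top - 0.7), cfg.port_radius,
                      cfg.ao_pressure, cfg.ao_resistance),
    ]
    # ports must sit strictly inside their chambers
    if not (cfg.ao_left + 0.35 < ports[1].center[0] < cfg.ao_right - 0.35):
        raise ValueError("AO port support intersects the conduit walls")
    return model, bstate, ports, sched


def ventricle_wall_indices(model: FiberModel) -> np.ndarray:
    """Indices of the ventricular free-wall chain (the first chain built)."""
    # the ventricular wall is the contiguous leading block of "ventricle"
    # group springs; recover its point range from them
    sel = model.spring_group == "ventricle"
    pts = np.union1d(model.spring_i[sel], model.spring_j[sel])
    return pts


# ---------------------------------------------------------------------------
# 3-D smoke fixture

def make_ellipsoid_membrane_3d(
    semiaxes=(2.0, 2.0, 3.0),
    center=(4.0, 4.0, 4.0),
    n_theta: int = 16,
    n_phi: int = 8,
    stiffness: float = 1.0e3,
) -> tuple[FiberModel, BoundaryState]:
    """Latitude/longitude spring shell on an ellipsoid (3-D smoke test only)."""
    a, b, c = semiaxes
    bld = _Builder(ndim=3)
    rows = []
    for ip in range(1, n_phi):
        phi = math.pi * ip / n_phi
        ring = []
        for it in range(n_theta):
            th = 2.0 * math.pi * it / n_theta
            ring.append(
                (
                    center[0] + a * math.sin(phi) * math.cos(th),
                    center[1] + b * math.sin(phi) * math.sin(th),
                    center[2] + c * math.cos(phi),
                )
            )
        off, _ = bld.add_chain(np.array(ring), stiffness, closed=True)
        rows.append(off)
    # meridional springs between consecutive rings
    for r0, r1 in zip(rows[:-1], rows[1:]):
        for it in range(n_theta):
            i, j = r0 + it, r1 + it
            L0 = float(np.linalg.norm(np.array(bld.pts[i]) - np.array(bld.pts[j])))
            bld._push([i], [j], [stiffness], [L0], np.array([""], dtype=object))
    return bld.build()


# ---------------------------------------------------------------------------
# ventricle-fixture analysis protocol

#: E-wave analysis window in normalized cycle time (brackets the early
#: filling jet; the mid-window matches the classic T ~ 0.13 snapshot)
E_WAVE_WINDOW = (0.08, 0.20)
#: interior analysis box of the ventricular chamber, cm (excludes the
#: valve slits and the aortic mouth, whose shear layers are not part of
#: the filling vortex pair)
LV_VORTEX_BOX = (6.0, 8.8, 4.8, 7.8)
#: Gaussian smoothing of the vorticity slice, in cells of the 64^2
#: reference grid (scaled with resolution), isolating chamber-scale cores
#: from fiber-scale shear noise
VORTEX_SMOOTH_CELLS = 2.5
#: vorticity threshold fraction for the E-wave pair count (the generic
#: connected-component default)
VORTEX_THRESHOLD = 0.2
#: KE-sampling ellipse over the ventricular chamber (center, semiaxes, cm)
LV_KE_ELLIPSE = ((8.0, 6.8), 1.6, 2.0)


def lv_kinetic_energy_mask(grid: GridSpec) -> np.ndarray:
    """Boolean mask of the ventricular-chamber KE sampling region."""
    (cx, cy), rx, ry = LV_KE_ELLIPSE
    X, Y = grid.meshgrid()
    return np.hypot((X - cx) / rx, (Y - cy) / ry) < 1.0


def run_ventricle_cycle(config: VentricleConfig | None = None,
                        transient: float = 0.2, n_cycles: int = 1):
    """Run one analysed cardiac cycle of the 2-D ventricle fixture.

    Executes the transient (ending at cycle phase 0) followed by
    ``n_cycles`` full cycles; the E-wave time-averaged velocity field, the
    ventricular-window kinetic-energy series, the port-rate series and the
    chamber-area series are collected over the LAST cycle (the earlier ones
    extend the spin-up toward the periodic regime).  Returns a dict with
    keys ``u_e_mean``, ``t_norm``, ``ke_lv``, ``Q_PV``, ``Q_AO``,
    ``volume``, ``grid``, ``config``.

    Everything is deterministic; the runtime is dominated by the
    ~T/dt coupled steps of the cycle.
    """
    from .core_fluid import FluidState
    from .diagnostics import kinetic_energy_slice, chamber_volume
    from .immersed_boundary import step_fsi

    cfg = config or VentricleConfig()
    model, bstate, ports, _ = make_ventricle_2d(cfg)
    grid, params = cfg.grid(), cfg.fluid()
    dt = params.dt
    state = FluidState.zeros(grid, t=-transient)
    bstate.t = -transient
    rates = None
    mask = lv_kinetic_energy_mask(grid)
    loop = model.chamber_loops["LV"]

    u_acc = np.zeros((grid.ndim, *grid.n))
    n_acc = 0
    sample_every = max(int(round(0.002 / dt)), 1)
    rec = {"t_norm": [], "ke_lv": [], "Q_PV": [], "Q_AO": [], "volume": []}
    n_per_cycle = int(round(cfg.T / dt))
    n_steps = int(round(transient / dt)) + n_cycles * n_per_cycle
    t_last = (n_cycles - 1) * cfg.T  # start of the analysed cycle
    for i in range(n_steps):
        state, bstate, info = step_fsi(state, bstate, model, ports, params,
                                       grid, port_rates=rates)
        rates = info.rate_vector
        if state.t < t_last:
            continue
        tn = model.t_norm(state.t)
        if E_WAVE_WINDOW[0] <= tn <= E_WAVE_WINDOW[1]:
            u_acc += state.u
            n_acc += 1
        if i % sample_every == 0:
            rec["t_norm"].append(tn)
            rec["ke_lv"].append(
                kinetic_energy_slice(state.u * mask[None], params.rho, grid,
                                     "total")
            )
            rec["Q_PV"].append(info.port_rates["PV"])
            rec["Q_AO"].append(info.port_rates["AO"])
            rec["volume"].append(chamber_volume(bstate.X[loop]))
    out = {k: np.asarray(v) for k, v in rec.items()}
    out["u_e_mean"] = u_acc / max(n_acc, 1)
    out["grid"] = grid
    out["config"] = cfg
    return out


def run_ventricle_e_window(config: VentricleConfig | None = None,
                           transient: float = 0.2) -> dict:
    """Short run covering just the transient and the E-wave window;
    returns the time-averaged E-window velocity field (for refinement
    studies where the full cycle is not needed)."""
    from .core_fluid import FluidState
    from .immersed_boundary import step_fsi

    cfg = config or VentricleConfig()
    model, bstate, ports, _ = make_ventricle_2d(cfg)
    grid, params = cfg.grid(), cfg.fluid()
    state = FluidState.zeros(grid, t=-transient)
    bstate.t = -transient
    rates = None
    u_acc = np.zeros((grid.ndim, *grid.n))
    n_acc = 0
    n_steps = int(round((transient + (E_WAVE_WINDOW[1] + 0.01) * cfg.T)
                        / params.dt))
    for _ in range(n_steps):
        state, bstate, info = step_fsi(state, bstate, model, ports, params,
                                       grid, port_rates=rates)
        rates = info.rate_vector
        if state.t >= 0:
            tn = model.t_norm(state.t)
            if E_WAVE_WINDOW[0] <= tn <= E_WAVE_WINDOW[1]:
                u_acc += state.u
                n_acc += 1
    return {"u_e_mean": u_acc / max(n_acc, 1), "grid": grid, "config": cfg}


def ventricle_vortex_cores(u_e_mean: np.ndarray, grid: GridSpec,
                           threshold_frac: float = VORTEX_THRESHOLD
                           ) -> tuple[int, int]:
    """Signed dominant-core counts of the E-wave filling vortex pair.

    The E-wave mean velocity field is curled, smoothed over the chamber
    scale, restricted to the ventricular interior box, and passed to the
    connected-component counter.
    """
    from scipy import ndimage

    from .diagnostics import count_vortex_cores, vorticity_z

    om = vorticity_z(u_e_mean, grid)
    sigma = VORTEX_SMOOTH_CELLS * grid.n[0] / 64.0
    om = ndimage.gaussian_filter(om, sigma, mode="wrap")
    x0, x1, y0, y1 = LV_VORTEX_BOX
    i0, i1 = int(x0 / grid.h), int(x1 / grid.h)
    j0, j1 = int(y0 / grid.h), int(y1 / grid.h)
    min_cells = 4 * (grid.n[0] // 64) ** 2
    return count_vortex_cores(om[i0:i1, j0:j1], threshold_frac, min_cells)


def smooth_periodic(x: np.ndarray, width: int) -> np.ndarray:
    """Periodic moving average (width in samples) for cycle series."""
    k = np.ones(width) / width
    xx = np.concatenate([x[-width:], x, x[:width]])
    return np.convolve(xx, k, "same")[width:-width]


def ventricle_ke_peak_times(t_norm: np.ndarray, ke_lv: np.ndarray,
                            smooth_width: int = 15,
                            prominence_frac: float = 0.1) -> list[float]:
    """E/A/S peak times of the ventricular KE waveform.

    The raw series carries fiber-scale jitter, so it is smoothed with a
    ~0.04 T periodic moving average before prominence-based detection.
    """
    from .diagnostics import detect_ke_peaks

    order = np.argsort(t_norm)
    return detect_ke_peaks(t_norm[order],
                           smooth_periodic(ke_lv[order], smooth_width),
                           prominence_frac)
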