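"""Hemodynamic analysis surface: the quantities a chamber-flow study reports.

Operates on dense velocity/pressure fields (from the solver or from an
external 4-D velocimetry source such as phase-contrast MRI, through
``ibcms.io.load_velocity_volume``) and on boundary-point loops:

* z-vorticity of a 2-D slice, via centered periodic differences;
* slice kinetic-energy (max or total of the 1/2 rho |u|^2 density);
* chamber area/volume and stroke volume;
* non-dimensional flow rate Q* = Q T / V_stroke;
* vortex-core counting by signed thresholded connected components
  (periodic 8-neighbor labelling);
* peak detection for the E/A/S kinetic-energy waveform.

NaN entries in external velocity arrays (masked voxels) are tolerated: KE
reductions ignore them, and vorticity propagates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from shapely.geometry import LinearRing

from .core_fluid import GridSpec

__all__ = [
    "DiagnosticSeries",
    "vorticity_z",
    "kinetic_energy_slice",
    "chamber_volume",
    "nondimensionalize_flow",
    "count_vortex_cores",
    "detect_ke_peaks",
]


@dataclass
class DiagnosticSeries:
    """Per-step time series accumulated over a run.

    t is absolute time (s), t_norm the position in the normalized cycle;
    Q holds one series per port (cm^2/s in 2-D, cm^3/s in 3-D);
    ke_max / ke_total per sample (erg/cm^3 density max; erg per unit depth
    total in 2-D); chamber_volume in cm^2 (2-D) or cm^3.
    """

    t: list = field(default_factory=list)
    t_norm: list = field(default_factory=list)
    Q: dict = field(default_factory=dict)
    ke_max: list = field(default_factory=list)
    ke_total: list = field(default_factory=list)
    chamber_volume: list = field(default_factory=list)

    def append(self, t, t_norm, rates: dict, ke_max=np.nan, ke_total=np.nan,
               chamber_volume=np.nan):
        if self.t and t <= self.t[-1]:
            raise ValueError("time samples must be strictly increasing")
        self.t.append(float(t))
        self.t_norm.append(float(t_norm))
        for name, q in rates.items():
            self.Q.setdefault(name, [np.nan] * (len(self.t) - 1)).append(float(q))
        for name in self.Q:
            if name not in rates:
                self.Q[name].append(np.nan)
        self.ke_max.append(float(ke_max))
        self.ke_total.append(float(ke_total))
        self.chamber_volume.append(float(chamber_volume))

    def arrays(self) -> dict:
        out = {
            "t": np.array(self.t),
            "t_norm": np.array(self.t_norm),
            "ke_max": np.array(self.ke_max),
            "ke_total": np.array(self.ke_total),
            "chamber_volume": np.array(self.chamber_volume),
        }
        for name, q in self.Q.items():
            out[f"Q_{name}"] = np.array(q)
        return out

    def stroke_volume(self) -> float:
        """Max minus min chamber volume over the recorded cycle."""
        cv = np.asarray(self.chamber_volume, dtype=float)
        cv = cv[np.isfinite(cv)]
        if cv.size == 0:
            raise ValueError("no chamber-volume samples recorded")
        return float(cv.max() - cv.min())


def vorticity_z(u_slice: np.ndarray, grid: GridSpec) -> np.ndarray:
    """omega_z = dv/dx - du/dy on a periodic 2-D slice of (u, v)."""
    if u_slice.ndim != 3 or u_slice.shape[0] < 2:
        raise ValueError("expected a (2, nx, ny) velocity slice")
    h = grid.h
    v = u_slice[1]
    u = u_slice[0]
    dvdx = (np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)) / (2 * h)
    dudy = (np.roll(u, -1, axis=1) - np.roll(u, 1, axis=1)) / (2 * h)
    return dvdx - dudy


def kinetic_energy_slice(
    u_slice: np.ndarray,
    rho: float,
    grid: GridSpec,
    mode: str = "max",
    floor: float | None = None,
) -> float:
    """Kinetic energy of a 2-D slice from its 1/2 rho |u|^2 density.

    mode="max" returns the maximum density over the slice (erg/cm^3);
    mode="total" integrates it (x h^2 per cell; erg per cm of depth).
    An optional ``floor`` zeroes densities below it before reduction
    (visualization parity with thresholded energy maps).  NaN cells are
    ignored.
    """
    ke = 0.5 * rho * np.sum(np.square(u_slice), axis=0)
    if floor is not None:
        ke = np.where(ke < floor, 0.0, ke)
    if mode == "max":
        return float(np.nanmax(ke)) if np.any(np.isfinite(ke)) else 0.0
    if mode == "total":
        return float(np.nansum(ke)) * grid.h**2
    raise ValueError("mode must be 'max' or 'total'")


def chamber_volume(X_loop: np.ndarray, faces: np.ndarray | None = None) -> float:
    """Enclosed area (2-D) or volume (3-D) of a chamber boundary.

    In 2-D, ``X_loop`` is the ordered polygon of chamber-wall points and
    the shoelace area is returned; orientation is ignored (absolute value)
    and a self-intersecting loop raises.  In 3-D, ``X_loop`` holds the
    surface vertices and ``faces`` the (F, 3) triangle index array of a
    closed surface; the divergence-theorem volume |sum det(v0, v1, v2)/6|
    is returned.
    """
    X_loop = np.asarray(X_loop, dtype=float)
    if X_loop.ndim != 2 or X_loop.shape[0] < 3:
        raise ValueError("need at least 3 loop points")
    if X_loop.shape[1] == 2:
        ring = LinearRing(X_loop)
        if not ring.is_simple:
            raise ValueError("chamber loop is self-intersecting")
        x, y = X_loop[:, 0], X_loop[:, 1]
        return float(
            0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        )
    if X_loop.shape[1] == 3:
        if faces is None:
            raise ValueError("3-D chamber volume needs a triangle face array")
        tri = X_loop[np.asarray(faces, dtype=int)]  # (F, 3, 3)
        return float(abs(np.einsum("fi,fi->", tri[:, 0],
                                   np.cross(tri[:, 1], tri[:, 2])) / 6.0))
    raise ValueError("points must be 2-D or 3-D")


def nondimensionalize_flow(Q, T: float, stroke_volume: float):
    """Q* = Q T / V_stroke (sign-preserving)."""
    if stroke_volume <= 0:
        raise ValueError("stroke volume must be positive (degenerate cycle)")
    return np.asarray(Q, dtype=float) * T / stroke_volume


def _periodic_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected labelling with periodic wrap via union-find merge."""
    structure = np.ones((3, 3), dtype=int)
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return lab, 0
    parent = np.arange(n + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    nx, ny = mask.shape
    for j in range(ny):  # x seam, 8-neighborhood
        a = lab[-1, j]
        if not a:
            continue
        for dj in (-1, 0, 1):
            b = lab[0, (j + dj) % ny]
            if b:
                union(a, b)
    for i in range(nx):  # y seam
        a = lab[i, -1]
        if not a:
            continue
        for di in (-1, 0, 1):
            b = lab[(i + di) % nx, 0]
            if b:
                union(a, b)
    roots = np.array([find(a) for a in range(n + 1)])
    remap = np.zeros(n + 1, dtype=int)
    uniq = np.unique(roots[1:])
    for new, r in enumerate(uniq, start=1):
        remap[roots == r] = new
    remap[0] = 0
    return remap[lab], len(uniq)


def count_vortex_cores(
    omega: np.ndarray,
    threshold_frac: float = 0.2,
    min_cells: int = 4,
) -> tuple[int, int]:
    """Count dominant vortex cores of each sign in a vorticity slice.

    Cells with |omega| > threshold_frac * max|omega| are labelled by
    8-neighbor periodic connectivity, separately per sign; components
    smaller than ``min_cells`` cells are discarded.  Returns
    (n_positive, n_negative); an all-zero field gives (0, 0).
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must lie in (0, 1)")
    omega = np.asarray(omega, dtype=float)
    peak = float(np.nanmax(np.abs(omega))) if omega.size else 0.0
    if peak == 0.0 or not np.isfinite(peak):
        return (0, 0)
    thr = threshold_frac * peak
    counts = []
    for sign in (1.0, -1.0):
        mask = sign * omega > thr
        lab, n = _periodic_label(mask)
        kept = 0
        for comp in range(1, n + 1):
            if int(np.sum(lab == comp)) >= min_cells:
                kept += 1
        counts.append(kept)
    return (counts[0], counts[1])


def detect_ke_peaks(
    t_norm: np.ndarray,
    ke: np.ndarray,
    prominence_frac: float = 0.1,
) -> list[float]:
    """Locations (t_norm) of prominent maxima in a one-cycle KE series.

    A local maximum counts as a peak when its prominence is at least
    ``prominence_frac`` of the series maximum.  A constant series has no
    peaks.  The series is treated periodically, so a peak straddling the
    cycle seam is found once.
    """
    t_norm = np.asarray(t_norm, dtype=float)
    ke = np.asarray(ke, dtype=float)
    if t_norm.shape != ke.shape or ke.ndim != 1:
        raise ValueError("t_norm and ke must be matching 1-D arrays")
    finite = np.isfinite(ke)
    t_norm, ke = t_norm[finite], ke[finite]
    if ke.size < 3:
        return []
    span = float(ke.max() - ke.min())
    if span == 0.0:
        return []
    # periodic handling: tile three cycles, keep peaks from the middle one
    n = ke.size
    ke3 = np.concatenate([ke, ke, ke])
    idx, _ = signal.find_peaks(ke3, prominence=prominence_frac * float(ke.max()))
    keep = idx[(idx >= n) & (idx < 2 * n)] - n
    return sorted(float(t_norm[i]) for i in keep)
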