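# Methods

`ibcms` simulates incompressible flow in elastic cardiac-like chambers with
the diffuse-interface immersed boundary method, driven by fixed-pressure
reservoir ports, and reports the hemodynamic quantities used in
left-ventricle flow analysis. This note records the model, the numerical
choices, the synthetic fixtures and their calibration, and what the tests
do and do not demonstrate.

## Governing model

The fluid is governed by the incompressible Navier–Stokes equations on a
periodic Cartesian box (CGS units throughout),

    rho (u_t + u . grad u) = -grad p + mu lap u + f,     div u = q,

where `f` is the body-force field exerted by the immersed elastic
boundaries and `q` is a prescribed divergence realizing localized
sources/sinks (the reservoir ports). Defaults `rho = 1.0 g/cm^3` and
`nu = 0.03125 cm^2/s` are the standard blood-analog values for this class
of heart model. The flow is laminar; no turbulence model is used.

The boundary is a Lagrangian spring network `X(s, t)`. Spring (i, j) with
stiffness `k(t)` and rest length `L0(t)` carries tension
`k (|Xj - Xi| - L0|)` along the connector; tether (target) points add
`k_teth (X_target - X)`, optionally with a slack length so the tether only
engages beyond a free excursion (cord-like constraints). Coupling in both
directions uses the standard 4-point regularized delta function: force
spreading and velocity interpolation are exact discrete adjoints, and the
kernel's moment identities (partition of unity, zero first moment) hold
for every sub-grid offset, which makes total force exact and linear
velocity fields interpolate exactly.

Activation (contraction and relaxation) modulates `k` and `L0` per fiber
group through C^1 piecewise-cosine envelopes over the normalized cycle
time `t/T mod 1`, with diastole on 0–0.75 T and systole on 0.75–1.0 T.

## Discretization

* Collocated cell-centered grid, centers at `(i + 1/2) h`, fully periodic;
  cells per axis a power of two.
* Advection: skew-symmetric centered differences (discretely
  energy-conserving).
* Viscosity: Crank–Nicolson, solved exactly in spectral space with the
  true Laplacian symbol (unconditionally stable).
* Projection: FFT Poisson solve with the symbol of the composed
  centered-difference divergence∘gradient stencil, so the projected field
  satisfies the discrete divergence constraint to roundoff (measured
  ~1e-15 relative; asserted at 1e-10). Pressure gauge: zero spatial mean.
  The symbol's null modes (invisible to centered differences) are snapped
  to exactly zero to avoid 1e28-fold amplification of float roundoff in
  `sin(pi)`.
* Coupled step: the classical two-stage time-centered cycle — forces at
  `X^n` drive a half step; forces at `X^(n+1/2)` and midpoint advection
  drive the full step; fibers move with the time-centered velocity
  `(u^n + u^(n+1))/2` interpolated at `X^(n+1/2)`. Formal second order;
  the Taylor–Green benchmark shows the decay-rate error shrinking ~4x per
  dt halving and < 1% at the default step.
* Near-Nyquist spectral filter: the collocated centered-difference scheme
  cannot damp odd-even (checkerboard) modes, which point forces from
  ~10^3 fiber springs continually re-excite. The predictor therefore
  applies `exp(-(dt/tau_f) (|k|/k_max)^16)` with `tau_f = 2e-4 s`. The
  exponent leaves resolved scales untouched (at `k_max/4` the damping
  exponent is ~1e-10 of its Nyquist value); the Taylor–Green k = 1 mode is
  unaffected to machine precision. Disable with `filter_time=None`.
* CFL guard: steps with advective Courant number > 0.9 raise, reporting
  the offending value.
* Default time step `dt = T/32768 = 2.44e-5 s` for the cardiac fixture
  (the conventional per-beat step count at T = 0.8 s); the limiting
  factor at 64^2 is the explicit treatment of the stiffest wall springs,
  which this dt clears with a ~7x margin.

## Reservoir ports

Each vascular opening exchanges volume with a fixed external reservoir
through a resistance: `Q = (P_res - p_local)/R`, positive into the domain.
`p_local` is the blob-weighted mean pressure over the port support (same
kernel shape as the boundary coupling, normalized to unit integral), and
is gauge-relative to the domain mean — the exterior fluid far from the
chambers sits near gauge zero, so reservoir values read approximately as
pressures relative to the pericardial exterior. Rates are realized as a
prescribed divergence `q = sum_k Q_k B_k` plus a uniform background that
zeroes the net integral exactly (periodic solvability); the alternative of
routing the residual through a designated reservoir was considered and
rejected as more intrusive.

The instantaneous rate law is numerically ill-posed under the projection
(the pressure response to a rate change scales like `rho/dt`), so each
port rate relaxes toward its target with a first-order time constant
(default 10 ms), representing the inertance of the blood column in the
opening. The steady state is exactly `Q = (P_res - p_local)/R`; the
two-port exchange test recovers `dP/(R_in + R_out)` to ~0.01%.

Reservoir pressures are constant over the cycle (the model family's
convention): PV 15 mmHg, AO 80 mmHg in the ventricle fixture; SVC/IVC 100
and PA 5 mmHg are available for user-defined right-heart ports. 1 mmHg =
1333.22 dyn/cm^2.

## Fixtures

All fixtures are deterministic functions of their configuration; no
randomness exists anywhere in the core.

**Ellipse membrane** — closed tension ring (`rest_length_factor = 0`), the
canonical verification geometry: area conservation (< 1% drift over 2000
steps at the default 256 points / dt 1e-4), relaxation toward a circle,
and the Laplace pressure jump `dp = T/r` (matched within 5%; measured
~0.6% at 64^2).

**Cylinder wake** — a rigid cylinder (stiffly tethered ring, D = 2 cm) in
a stream driven by two balanced reservoir ports placed half a domain
apart, so the direct and periodic-wrap paths have equal hydraulic length
and each carries half the exchanged flux. A deterministic transverse
pulse seeds the antisymmetric mode to skip most of the linear-growth
transient. With `nu = 0.16` the measured upstream Reynolds number is ~85
and the wake saturates into a time-periodic street (probe autocorrelation
secondary peak ~0.7, Strouhal ~0.12 — low-side of the classic 0.16, as
expected for an effective diameter thickened by the diffuse interface and
25% lateral confinement); with `nu = 0.7` (Re ~ 15–20, below the ~47
shedding threshold) the wake is steady to 5e-4 relative fluctuation.

**Two-chamber ventricle (primary)** — a 16 x 16 cm box at 64^2 holding an
elastic atrium (ellipse arc) over a conical ventricle (ellipse arc, apex
down), joined by a 1.4 cm mitral opening, with a dead-end aortic conduit
on the ventricle's right shoulder. The PV port (15 mmHg) sits inside the
atrium; the AO port (80 mmHg) inside the conduit — a port in a closed
cavity self-limits, so no outlet to the far field is needed. Design
choices that proved load-bearing at this resolution:

* *Multi-layer walls.* A single fiber curtain leaks visibly under tens of
  mmHg held for most of a cycle. Pressure-bearing walls are therefore
  double curtains offset by h/2 (ventricular free wall: triple,
  tangentially staggered), with point spacing h/4 — denser than the h/2
  anti-leakage bound. Net port throughput over a converged cycle is ~6%
  of the gross exchange, i.e. wall seepage is small but not zero.
* *Stiffness as rigidity.* Spring stiffness is configured as extensional
  rigidity K (dyn), with per-spring `k = K/segment`, so wall load capacity
  is independent of the discretization density.
* *Valves.* Each valve is a pair of soft leaflet chains hinged at stiffly
  tethered rim points, crossed at rest (tips overlap the midline by
  0.35–0.45 cm): forward pressure swings them apart, reverse pressure
  deepens the crossing, which blocks the opening without any
  leaflet-contact algorithm (contact handling is deliberately out of
  scope). Slack cords — chordae tendineae for the mitral tips (anchors
  below the valve plane), retaining cords into the conduit for the aortic
  tips — engage only on reverse excursion and prevent prolapse. The
  valves still cannot seal perfectly: a systolic mitral/PV backflow of a
  few cm^2/s remains, faithfully mirroring the imperfect closure reported
  for the anatomical model family, and the diastolic aortic back-leak is
  ~1 cm^2/s against a 65 mmHg head.
* *Activation.* The ventricular group contracts over systole (k x1.8,
  L0 x0.25, cosine ramp 0.06 T, release 0.12 T into diastole); diastolic
  filling is elastic recoil of the wall (springs plus rest-shape tethers).
  The atrial group fires a cos^2 pulse centered at 0.5 T (width 0.24 T,
  k x2.5, L0 x0.22). Depths and the port resistances (PV 1.2, AO 1.5
  mmHg s/cm^3) were calibrated once so the chamber fills over roughly the
  first half of diastole and ejects during the 0.25 T systole with
  left-ventricular pressure crossing the aortic reservoir value
  (~90 mmHg peak); they are ordinary config fields, not measured values.

With these defaults the converged (second) cycle shows: stroke area
~3.5 cm^2 returning to its start value within a few percent; PV inflow
through early diastole, a transient PV reversal around the atrial kick,
and PV outflow during systole; aortic ejection pulses to ~-10 cm^2/s; and
left-ventricular pressure from ~-5 mmHg (early-diastolic suction) to
~90 mmHg (systole) with the conduit holding 77–83 mmHg throughout.

## Analysis protocol (frozen constants)

The chamber interior is chaotic at this resolution — thin valve-slit jets
reach O(100) cm/s while the organized filling jet is O(10) cm/s — so the
two headline diagnostics are defined on noise-suppressed reductions, with
all constants frozen in `ibcms.fixtures`:

* *E-wave vortex pair*: velocity is time-averaged over t/T in
  [0.08, 0.20] (bracketing the classic mid-E snapshot), curled, smoothed
  with a Gaussian of 2.5 cells (64^2 reference, scaled with resolution),
  restricted to the chamber-interior box x in [6.0, 8.8], y in [4.8, 7.8]
  (excluding the valve slits and the aortic mouth), and passed to the
  signed connected-component counter at the generic 0.2 threshold with a
  4-cell (resolution-scaled) minimum size. The result, exactly one core
  of each sign, is unchanged on a 128^2 / dt-halved repeat; the
  smoothing scale is the coarsest-common choice at which both resolutions
  isolate the same two chamber-scale cores from fiber-scale shear.
* *E/A/S kinetic-energy waveform*: the 1/2 rho |u|^2 integral over an
  ellipse inscribed in the ventricular chamber (top at the valve plane,
  so the upward systolic regurgitant jet core is excluded while the
  downward filling jet is kept), sampled every 2 ms, smoothed with a
  ~0.04 T periodic moving average, then peak-detected at the default 0.1
  prominence fraction. Three peaks result (E ~0.12, A ~0.53, S ~0.9 of
  the cycle), with the E peak above the A peak. The waveform is measured
  on the second simulated cycle (one spin-up cycle after a 0.25 T
  systolic transient), i.e. the beat after the first — the
  near-periodic regime.

`count_vortex_cores` uses 8-neighbor connectivity made periodic by
union-find across both seams. `detect_ke_peaks` treats the cycle
periodically (three-fold tiling) so a peak straddling the seam is found
once. `chamber_volume` is the shoelace area of the wall-point loop and
rejects self-intersecting loops.

## What the synthetic fixtures do and do not show

The fixtures emulate the *mechanistic skeleton* of chamber hemodynamics —
pressure-driven filling and ejection through check valves, jet roll-up
into a diastolic vortex pair, the three-phase energy waveform, reservoir
afterload — on a 2-D desk-scale geometry with ~10^3 boundary points.
They do not emulate: 3-D vortex-ring dynamics (a 2-D pair is the planar
analog), anatomical fiber architecture or its regional material
properties, physiological flow magnitudes (stroke areas here are cm^2 per
unit depth; no attempt is made to match printed cm^3/s magnitudes), the
boundary-layer interaction that differentiates left and right vortex
growth, or valve leaflet contact. Passing tests therefore demonstrate
correct solver mechanics and the qualitative flow structure of the model
family, not clinical fidelity.

## Numerical edge cases and conventions

* Springs with coincident endpoints contribute zero force (defined limit).
* Fiber positions are stored unwrapped; wrapping happens only in the
  kernel stencil, keeping spring lengths well-defined across the seam.
* A port whose radius is below 2h raises (unresolvable blob); overlapping
  port supports raise; a nonzero-mean Poisson right-hand side raises
  (unbalanced sources).
* NaNs in external velocity volumes (masked voxels) propagate: KE
  reductions ignore them, vorticity carries them.
* Everything downstream of a configuration is deterministic; identical
  configs give bitwise-identical containers and series, and restart from
  a checkpoint continues bitwise-identically (time is step-indexed).
* Problem sizes used by the shipped analyses: 64^2 cells, ~10^3 boundary
  points, 2.2 cycles at dt = T/32768 for the cardiac protocol; 128^2 at
  dt = T/65536 for the refinement window; 128 x 32 cells for the wake
  study. These keep a full analysis run in minutes on one core while
  leaving the production-scale 128^3 configurable.

## Known limitations

* The KE waveform's A-peak prominence is modest (~1.5x its local
  baseline); detector-parameter changes (smoothing width, prominence)
  away from the documented defaults can merge or split the marginal
  peaks.
* Chamber sealing is resolution-limited: wall seepage and valve leaks
  scale with the pressure head and would shrink substantially at 128^2+.
* The 3-D path is exercised only by a smoke test (ellipsoid shell at
  32^3); the 2-D fixtures are the validated surface.
* The cylinder Strouhal number (~0.12) reflects confinement and interface
  thickening; it is a regime indicator here, not a benchmark value.
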