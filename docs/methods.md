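# Methods

## Scope and model assumptions

The package treats a carrying pole as two independent Euler–Bernoulli
cantilevers fixed at the functional centre (the balance point on the
carrier's shoulder), each loaded by a point mass at its attachment peg.  The
loaded end is modelled as a linear single-degree-of-freedom
mass–spring–damper, `m y'' + c y' + k y = m g`, with viscous damping.  The
assumptions this brings:

* no net translation or rotation at the clamp (an idealisation of the
  carrier's stabilising hand);
* deflection linear in load and cubic in position — the cantilever surface
  `δ = a (3 m g x_L x² − m g x³)`, `a = 1/(6EI)`;
* a section constant along the pole when converting rigidity to stiffness
  (`k = 3EI/x_L³`); taper and growth-node thickenings are treated as
  perturbations, characterised but not modelled in the beam equation;
* viscous (velocity-proportional) energy loss; the identified ζ absorbs
  whatever the true loss mechanism is;
* bending only downward (the functional direction).  The bench's limit
  stops that block upward motion are *not* simulated; the linear model is
  used throughout, which is adequate because oscillation amplitudes decay
  quickly at the observed ζ ≈ 0.01.

## Estimation procedures

**Ring-down identification** (`vibration`).  Acceleration is doubly
integrated by cumulative trapezoids (release from rest ⇒ zero initial
conditions) and linearly detrended, since any sensor bias integrates to
quadratic drift; a warning fires when the quadratic residual still
dominates (threshold: 5× the oscillation scale — a deliberate drift alarm,
not an error).  The carrier frequency is taken from the acceleration
periodogram (white sensor noise, no integration drift), and the
displacement is band-passed 0.7–1.4× that frequency with a zero-phase
2nd-order Butterworth before peak picking.  The band is generous relative
to the decay bandwidth ζω_n (~0.2 rad/s against a ~19 rad/s carrier), so
the envelope is preserved while the low-frequency random walk from
integrated noise is removed.  Peaks are local maxima of the sign-normalised
oscillation with prominence ≥ 5% of the largest peak and spacing ≥ 0.7
periods.  The damped frequency is the reciprocal mean per-cycle interval,
with an interval spanning multiple cycles (a missed peak) counted by its
multiplicity.  The logarithmic decrement is the *median* of per-cycle
`ln(y_i/y_{i+1})` over strictly decreasing pairs (non-decreasing pairs are
skipped, not clipped), and ζ = φ/√(4π² + φ²).  The first half-cycle (release
transient) is discarded.

**Deflection surface** (`deflection`).  The model is linear in the single
coefficient *a*, so the least-squares optimum is closed-form regression
through the origin on `u = m g (3 x_L x² − x³)` — identical to the optimum
of an iterative nonlinear fit, but deterministic.  The 95% CI comes from
the t-distribution on the residual variance with n−1 degrees of freedom.
Stiffness is read from the loading branch; hysteresis from trapezoidal
integration of the loading/unloading loop on a common deflection grid
(unloading forces exceeding loading are clipped with a warning).

**Inverse resonance fit** (`dynamics`).  `f = √(1−ζ²)·√(k/m)/(2π)` is
linear in √k, so the fit regresses frequency on `√(1−ζ²)/(2π√m)` — the √k
parameterisation also enforces positivity.  The standard error of k follows
by the delta method; the residual SE is reported in Hz and as a percentage
of the model-predicted frequency range over the observed loads (the range
convention is a documented choice; max−min of the predictions).  ζ is held
fixed at the pole's median measured value: √(1−ζ²) deviates from 1 by under
0.02% at the observed damping, so this choice is numerically immaterial.

**Section properties** (`geometry`).  Polygon area, centroid and second
moment use the shoelace-moment sums; signed quantities internally (either
winding accepted), magnitudes reported, hollow sections as outer minus
lumen contour sums.  The partial-tube model evaluates segment integrals of
the chord width `2√(R²−y²)` over `y ∈ [−R, −R+h]` by adaptive quadrature
(relative tolerance 1e-10) and applies the parallel-axis theorem.  Meshes
are sliced with trimesh at 5 mm stations (the CT analysis interval) along
the longest bounding-box axis; empty or degenerate stations are skipped
with a warning.  A pole is characterised by the mean section over a
fractional axial window, default the middle 20% of length — a proxy for
the internode centre region, since node coordinates are not generally
available.  Sections lacking a lumen contour (e.g. at nodes) are treated as
solid.

## Key parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| g | 9.81 | m s⁻² | gravitational acceleration |
| r/R | 0.73 (range 0.69–0.78) | — | lumen proportionality for hand-measured sections |
| basket mass | 0.480 | kg | tare added to each nominal per-end load |
| load schedule | 0.480 + 2.225·n, n = 1…9 | kg | per-end masses of the test protocol |
| slice interval | 5 | mm | axial spacing of mesh sections |
| peak prominence | 5% of largest peak | — | ring-down peak filter |
| analysis band | 0.7–1.4 × carrier | — | displacement band-pass |
| x_L convention | L/2 | m | lever arm when per-end functional-centre arms are unknown |

The half-length lever-arm convention is used for table-level stiffness
summaries; per-end arms can be supplied where the functional-centre offset
was measured (the front end is typically shorter, hence stiffer).

## Synthetic data: what it emulates, what it does not

`synthetic` generates the three bench inputs from one ground-truth
parameter set (default: E = 18 GPa, R = 31.5 mm, h = 22 mm, r = 0.73R,
L = 1.40 m, x_L = 0.65/0.75 m, ζ = 0.011, nodes every 300 mm, 3% end
taper — a typical surveyed pole).  Vibration traces are the *exact*
underdamped step response sampled at 100 Hz for 30 s; deflection records
follow the beam surface with the unloading branch scaled by (1+ε) in
deflection, giving an analytic loop-area ratio ε/(1+ε).  Noise is additive
Gaussian — 1% of the peak acceleration, 0.2 mm on markers — emulating
sensor and digitisation error.  Meshes are lofted partial tubes; because
the chord cut opens the lumen (h > R − r), every slice is a single C-shaped
contour and the loft stays watertight with fixed topology.  Growth nodes
are cosine-profile lumen constrictions (wall thickenings) rather than fully
solid slices, keeping that topology constant; the attached analytic ground
truth uses the same radius profiles, so slice-versus-truth comparisons are
exact up to mesh discretisation (≤1e-3 relative at 64 arc points/side).

In `gen_pole` the rigidity that drives the deflection and vibration
generators is computed from the *generated geometry*: the mean analytic
I_zzc over the same axial window the pipeline uses.  Every stage can then
be checked against one parameter set without an arbitrary choice of which
section "is" the pole.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real bench data: the upward limit-stop
nonlinearity, amplitude-dependent or non-viscous damping, marker-tracking
outliers, sensor bias instability beyond a constant, clamp compliance, and
material heterogeneity along the culm.  Recovery results certify the
estimators under the stated noise model only.

## Numerical choices and degenerate inputs

* Polygon operators require ≥3 vertices and nonzero signed area; degenerate
  sections raise typed errors, and degenerate *mesh slices* are skipped
  with a logged warning rather than aborting a whole pole.
* The partial tube requires 0 ≤ r < R and 0 < h ≤ 2R; the full-annulus
  limit (h = 2R) and the solid semicircle (r = 0, h = R) reproduce their
  closed forms to 1e-8.
* Fits raise on rank-deficient designs (single load or single marker;
  single load level in the resonance fit).
* Ring-down analysis raises `InsufficientCyclesError` below two usable
  peaks; `damping_ratio` requires φ ≥ 0.
* Sample standard deviations use n−1 throughout; cohort percent differences
  are relative to the lab (directly measured) cohort mean.
* Problem sizes in the test suite — 0.5 m meshes at 10–25 mm stations,
  24–64 arc points, 30 s traces at 100 Hz, 20–100 Monte-Carlo seeds — were
  chosen as the smallest sizes at which the discretisation error is an
  order of magnitude below each tolerance being verified.

## Known limitations

* The two-cantilever idealisation ignores coupling through the clamp and
  any rotation at the shoulder.
* The partial-tube lumen ratio r = 0.73R is a population average; per-pole
  deviation propagates ~4ΔR/R into I for thin sections.
* The inverse resonance fit identifies k only up to the assumed lever-arm
  convention when E is back-computed from it.
* Hysteresis from loading/unloading tables is a quasi-static loop measure;
  it is related to, but not identical with, the viscous ζ identified from
  ring-downs (the two are reported separately, never reconciled).
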