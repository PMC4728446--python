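# Methods

## The three-rod force-balance model

One half of a metaphase spindle is represented by three inextensible
elastic rods in a plane. The spindle long axis is the x axis and the left
pole the origin. Rod p (the merged bundle of k-fibre plus bridging-fibre
microtubules) runs from the pole (0, 0) to the junction (x_j, h_j); rod k
(the terminal k-fibre segment) from the junction to the kinetochore
(x_k, h_k); rod b (the central part of the bridging fibre) from the
junction to the spindle midpoint (L/2, h). The right half follows by
reflection about x = L/2.

External loads are a horizontal inward force F₀ at the pole, a horizontal
tension F_k applied at the kinetochore (the centromeric link to the sister
pulls along the sister–sister axis), and a clamping moment M₀ at the pole.
Taking moments of these loads about a material point at height y gives

    M_p(y) = M₀ + F₀ y,
    M_k(y) = −F_k (y − h_k),
    M_b(y) = (F₀ + F_k) y − F_k h_k + M₀,

which satisfy M_p = M_k + M_b — the junction is in moment balance, so the
three rods form a consistent static structure. With curvature positive
counter-clockwise, the internal moment convention fixed by these load
directions yields, in Cartesian form,

    κ_i y″ = −M_i(y) (1 + y′²)^{3/2},   i ∈ {p, k, b}.

The sign is not a free choice: with the opposite sign rod p steepens away
from its initial 64° pitch and no bounded shape exists.

Flexural rigidities are additive over the microtubules of a bundle,
κ_i = n_i κ₀ with n_p = n_k + n_b, reflecting the assumption that
microtubules may slide relative to one another as the bundle bends. A
quadratic scaling (fully crosslinked bundle, κ ∝ n²) is available through
`FibreArchitecture(coupling="quadratic")` but is not the default and is
not validated against reference values.

Integration uses the fixed-step explicit midpoint (RK2) scheme with 50
steps per rod, the method of the original analysis; the test suite checks
it against `scipy.integrate.solve_ivp` (DOP853, rtol 1e-12) to within
0.1%, and checks that halving the step changes endpoints by well under 1%.
Rods turning steeper than 86° abort with a parameterization-breakdown
error, since y(x) stops being a graph there.

## The inverse problem and its conditioning

The measurable quantities are geometric; the forces are not. The solver
therefore seeks (F₀, F_k, x_j) — with M₀ fixed to 0, since it trades off
against F₀ along a complementary direction — such that

1. y_b′(L/2) = 0 (reflection symmetry at the midplane),
2. y_k(x_k) = h_k (the rod ends on the kinetochore),
3. |atan y_k′(x_k)| = θ_k (the measured fibre angle at the kinetochore).

Both signs of the terminal slope occur in practice, so the third residual
is evaluated on both signed branches and the better branch is reported.

Two properties of this system shaped the solver design:

* **Near rank deficiency.** The residual Jacobian at a solution has
  condition number ~10⁶, with F_k along the near-null direction: shapes
  with F_k differing by tens of pN are nearly indistinguishable. Distinct
  exact roots can coexist a short distance apart along this direction.
  Consequently the kinetochore tension is an order-of-magnitude estimate;
  the pole force and junction position are much better determined. When the
  measured kinetochore-to-bridge distance d_bk is provided, it is used to
  select among materially distinct converged roots (the model's d_bk
  discriminates them); otherwise the lowest-residual root is returned.
* **Narrow curved valleys.** Plain multistart trust-region least squares
  escapes along the ill-conditioned direction and misses roots. The solver
  therefore runs three deterministic phases: (1) damped least squares from
  a small start grid (F₀ ∈ {10, 50, 100} pN, F_k ∈ {100, 300, 500} pN,
  junction 0.5–1.5 µm inside the kinetochore); (2) if nothing converged, a
  vectorized coarse scan of the full (F₀, F_k, x_j) box, keeping the best
  candidate per junction slice, each polished; (3) descent along the
  numerical null direction of the Jacobian from the running best point.
  Convergence requires every residual below its tolerance (10⁻³ µm for
  heights, 10⁻³ for slopes). Phase 1 resolves well-posed cases in under a
  second; the escalation adds ~40 s when needed. All phases are
  deterministic — no randomness enters the solve.

For fixed (F_k, x_j, M₀), sweeping the pole force against the
bridging-fibre thickness n_b reduces to a single-unknown root find on the
midpoint-symmetry condition. The compressed bridge admits higher buckling
modes for thin bridges (oscillatory equilibria); the sweep classifies each
root by the number of slope sign changes along rod b and tracks the
fundamental (mode-0) branch by continuation, anchored at a thickness where
that branch is unique. F₀ increases strictly with n_b along this branch
for all three reference parameter sets over n_b ∈ [10, 30] — a thicker
bridge needs a larger force to bend. Below n_b ≈ 10 two of the three sets
have no fundamental symmetric equilibrium at all, only higher modes, so
monotonicity is not defined there on a single branch. The bridgeless limit
n_b = 0 is singular (the tangency condition collapses into a vanishing
boundary layer); it is handled as a rigid-strut model in which the
junction must sit on the bridge's zero-moment line y* = (F_k h_k − M₀)/(F₀
+ F_k).

## Relation to the originally reported values

With the reference inputs (θ₀ = 64°, L = 11.1 µm, x_k = 5.05 µm, h_k =
5.0 µm, θ_k = 13.7°, n_k = 17, n_b = 14, κ₀ = 30 pN µm², M₀ = 0) the
model's exact equilibrium is F₀ ≈ 9.2 pN, F_k ≈ 162 pN with the junction
≈3.4 µm from the kinetochore — not the historically reported (33 pN,
280 pN, 0.75 µm), which violates the midpoint-symmetry condition under
direct forward integration of the printed moment set. The discrepancy is
resolved by the conditioning analysis: constructing an exact equilibrium
*at* the reported junction position (x_j = 4.3 µm, F_k = 300 pN) yields
F₀ = 31.7 pN with constraint targets h_k = 5.55 µm, θ_k = 21.0°, d_bk =
0.05 µm — every one within about one standard deviation of the measured
population values (5.0 ± 0.7 µm, 13.7 ± 10.1°, 0.24 ± 0.15 µm). In a
near-degenerate system, solving "until the outputs are consistent with the
experiment" (a tolerance criterion) and solving the mean values exactly
land on different points of a broad, shallow solution region. The package
solves the stated constraints exactly and reports residual diagnostics;
the practical interpretation of any single solution point should carry the
conditioning caveat above.

## Quantification layer

* **Intensity profiles.** Line scans are background-subtracted by the mean
  cytoplasmic level (given, stored, or estimated from 0.5-µm flanks), and
  peak areas are trapezoidal integrals over windows centred on the
  detected local maximum nearest the kinetochore midpoint, with default
  base widths 0.6 µm (bridging fibre) and 1.0 µm (k-fibre). Peak detection
  requires prominence at least twice the flank noise s.d. Because both
  windows cover ±2σ of their synthetic peaks, window truncation cancels in
  the intensity ratio.
* **Counts.** The bridge-to-k-fibre intensity ratio converts as
  I_b/I_k = r/(1−r) with r = I_b/I_bk, and the count estimate is
  n_b = round(n_k·r/(1−r)), rounding half away from zero; the unrounded
  value is `n_k * bridge_fraction(r)`.
* **Tracks.** The spindle axis is supplied explicitly (origin plus
  direction); all geometric readouts (sister tilt, interkinetochore
  distance and its relaxation over 4 s, perpendicular displacement
  positive away from the axis, stub length) are Euclidean and invariant
  under rigid motions applied jointly to track and axis. Times are matched
  to the nearest acquired frame within one frame interval, accommodating
  the 3.5–4.5 s acquisition spacing of the source recordings.
* **Angles.** Contour angles use a total-least-squares line through three
  consecutive points (~250 nm apart), reported as unsigned angles in
  [0°, 90°].

## Synthetic-data generator

The generator emulates the published population statistics, so its
defaults are the study conditions, not free dials.

* **Geometry** (per cell type): independent truncated normals with the
  measured means ± s.d. — HeLa: n_b 14±2, θ₀ 65.5±8.8°, θ_k 13.7±10.1°,
  d_bk 0.24±0.15 µm, d_k 1.05±0.32 µm, L 11.1±1.2 µm, h_k 5.0±0.7 µm;
  PtK1: n_b 6±1, θ₀ 52.6±8.4°, θ_k 21.2±10.2°, d_bk 0.20±0.10 µm, d_k
  1.92±0.54 µm, L 11.8±1.7 µm, h_k 4.0±0.6 µm. The kinetochore position
  follows from symmetry about the metaphase plate, x_k = L/2 − d_k/2.
* **Line scans**: Gaussian peaks on a flat cytoplasmic background, base
  widths 0.6/1.0 µm (σ = width/4), sampled at the 81-nm pixel size, with
  analytic areas set so I_b/(I_b+I_k) equals the target ratio (0.45 HeLa,
  0.20 PtK1); additive Gaussian noise at 2% of the background level by
  default, which reproduces the ±2-microtubule spread of the count
  estimate across replicate scans.
* **Ablation kinematics**: per cell, the proximal kinetochore's
  perpendicular excursion rises as a quarter sine to a cell-specific peak
  (population mean 0.32 µm at 11 s) and returns exponentially (τ = 20 s);
  the interkinetochore distance contracts linearly over 4 s by an amount
  centred on a logistic function of stub length (plateaus 0.25/0.05 µm,
  transition at 1 µm, width 0.2 µm — midpoint 0.15 µm at the default 1-µm
  stub, matching the measured mean relaxation); the sister pair tilts to a
  per-thickness-class angle at 4 s (2.9° for n_b≈3, 4.0° for n_b≈14,
  15.9° for n_b≈23). Between-cell spreads for quantities reported as mean
  ± s.e.m. over n cells use s.d. = s.e.m.·√n (0.29 µm for the peak
  excursion, 0.43 µm for the relaxation); cell-level effects are left
  untruncated so that population means stay calibrated. Frames are sampled
  at 4-s intervals with 25-nm isotropic positional noise. Because 11 s
  falls between frames, the mean displacement curve peaks at the 12-s
  frame at ~0.95 of the programmed amplitude — the same discretization a
  real 4-s acquisition imposes.
* **Contours**: solved shapes resampled at 250-nm arc spacing with
  isotropic Gaussian noise, feeding the angle and recovery tests.
* **Comets**: homogeneous Poisson event streams per direction class
  (defaults 1.9/min toward the cut site, 0.6/min opposite) with Gaussian
  velocities (13.1 ± 1.1 µm/min).

All generators accept a seed (or `numpy.random.Generator`) and are
byte-reproducible. What passing generator-based tests shows is that the
quantification layer is calibrated against known ground truth with the
published population spread; it does not establish anything about
segmentation, tracking, or optical effects (PSF, photobleaching, pixel
noise correlations), which are outside the generator's scope.

## Known limitations

* The kinetochore tension F_k is weakly identified by spindle shape: at
  50-nm contour noise the three-point angle extraction carries ~±10–15°
  error in θ_k and F_k recovery degrades to tens of percent or worse,
  while F₀ still recovers to a few percent. Population-level force claims
  should rest on F₀ and the junction position.
* Validity requires rods representable as graphs y(x) (slopes below 86°);
  extremely steep pole angles or junctions very close to the pole can
  leave the parameterization.
* Statics only: no microtubule dynamics, motor activity, crosslinker
  mechanics at the junction, or viscoelastic relaxation after severing —
  the cut-outcome rule (`predict_cut_outcome`) is the static before/after
  comparison: tension is retained iff the stub is strictly longer than the
  kinetochore-to-junction distance.
* Geometry parameters are sampled independently; no covariances are
  modelled because none are reported.
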