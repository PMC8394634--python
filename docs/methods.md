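# Methods

## Model and algorithm

The tomographic inverse problem is `y = A x + δ` with a nonnegative image
`x ∈ R_+^J` on a square grid, a sparse nonnegative projection operator
`A ∈ R_+^{I×J}`, and measured ray sums `y ∈ R_+^I`. Reconstruction
minimizes the extended power-divergence objective

V(x) = Φ_{γ,α}(y, Ax),  Φ_{γ,α}(p, q) = Σ_i ∫_{p_i}^{q_i} (s^γ − p_i^γ) s^{−γα} ds,

with γ > 0, α ≥ 0. The integrand has the sign of (s − p_i), so each term
is nonnegative and vanishes exactly at p_i = q_i. Closed forms follow from
the two-power antiderivative; the exponent poles γα = 1 and γα = 1 + γ get
dedicated branches (selected within 1e-12 of the pole to avoid catastrophic
cancellation in the 1/(1−γα) and 1/(1+γ−γα) factors). Terms with p_i = 0
converge iff γ(1−α) > −1 and otherwise make the sum +∞, which is returned
as `inf` rather than raised: it is the mathematically correct value, and
the reconstruction path never evaluates it (zero-measurement rays
contribute zero to the update numerator). Summation is in ascending ray
order for bitwise reproducibility. An adaptive-quadrature evaluator of the
defining integral (`epdm_quadrature`) serves as the oracle in tests.

The minimizing iteration multiplies each pixel by the ratio of two
backprojections,

f_j(w) = ξ_j/ζ_j,  ξ = Aᵀ[y^γ (Aw)^{−γα}],  ζ = Aᵀ[(Aw)^{γ(1−α)}],

raised to a relaxation exponent h (default 1; h = 0 degenerates to the
identity and is permitted for completeness). (γ, α) = (1, 1) recovers
classical MLEM exactly. The iteration is the multiplicative-Euler
discretization of the flow dx_j/dt = x_j log f_j(x), whose Lyapunov
function is V: along solutions dV/dt = −(ξ−ζ)ᵀ diag(x) (log ξ − log ζ) ≤ 0,
and on consistent data the true image is an asymptotically stable
equilibrium. The package exposes h but makes no convergence claim for
h ≠ 1; the discrete h = 1 iteration is verified empirically (monotone V on
consistent data) rather than by a discrete-time theorem.

## Geometry and projector

Parallel-beam, one ray per detector bin through the bin center, exact
ray/pixel intersection lengths by parametric grid traversal (Siddon-style),
vectorized per view. Conventions are fixed and documented in
`epdmct.geometry`: unit pixels centered on the isocenter, array row 0 at
the top with the y axis up, view angles equally spaced on the half-open
interval [0°, 180°), rays indexed view-major. Default detector spacing is
`image_size·√2 / n_bins`, so the detector array exactly covers the image
diagonal — with 184 bins on a 128-px grid that gives spacing ≈ 0.984 px,
consistent with a line (not strip) ray model. Rays that miss the image
square keep all-zero rows but are flagged in a validity mask and excluded
from divergence and update sums, which avoids 0/0 terms. The projector is
validated against a brute-force polygon-clipping oracle (shapely) to
1e-12 on small grids; the one caveat is a ray lying exactly on a pixel
boundary, a measure-zero configuration the standard geometries never
produce (even bin counts, irrational spacing).

## Phantom and noise generator

The simulator emulates the classic high-contrast head-phantom benchmark:
the ten-ellipse "modified Shepp–Logan" density table (values in [0, 1]),
rasterized by pixel-center membership without anti-aliasing, negative sums
clipped at 0. The rasterization agrees pixel-for-pixel with the published
reference rasterization except on edge-membership pixels (~5% at 400 px).
Noise is i.i.d. additive white Gaussian at a stated SNR in dB, with
negatives clipped to zero because the divergence and the update require
nonnegative data; the clipping is part of the generator's contract and is
recorded in the sinogram's provenance metadata alongside the seed.

Two SNR conventions are implemented because the dB figure alone does not
determine σ:

* `"peak"` (default): σ = max(y) / 10^(SNR/20), PSNR-style;
* `"power"`: σ² = mean(y²) / 10^(SNR/10), so the realized
  10·log10(Σy²/Σδ²) equals the nominal SNR up to sampling error
  (verified to 0.2 dB at I = 33,120).

The packaged benchmark protocol uses the peak reading at 30 dB
(σ ≈ 1.07 for the standard phantom sinogram, whose peak is ≈ 33.9). That
choice reproduces the published benchmark behavior — MLEM's
semiconvergence minimum well before iteration 200 and evaluation values on
the reported scale — whereas the mean-power reading (σ ≈ 0.43) yields a
much milder noise regime. Users comparing against other conventions can
switch with one argument.

What the generator does *not* emulate: Poisson counting statistics,
attenuation/beam-hardening physics, detector blur, scatter, or strip-ray
footprints. Passing tests therefore certify algorithmic behavior under the
stated additive-Gaussian line-integral model, not performance on raw
scanner data.

## Numerical policies

* Update powers are always computed as exp(γ·log y − γα·log Aw) with rays
  where y_i = 0 contributing exactly 0 to ξ. Direct powers are not safe:
  on noise-free data the rays with y_i = 0 drive the pixels outside the
  object support toward zero geometrically, and (A_i z)^{−γα} then
  overflows within ~50 iterations for α > 1.
* The iterate is floored at 1e-250 after each multiplicative step. Exact
  arithmetic keeps the iterate strictly positive forever; the floor only
  protects against floating-point underflow in regions the data drive to
  zero, and sits far below any imaging-relevant scale.
* A forward projection that vanishes on a valid ray, or a pixel seen by no
  valid ray (ζ_j = 0), raises an error naming the ray/pixel instead of
  being silently floored — silent flooring can mask projector bugs.
* The constant initial value defaults to mean(y)/mean(row sums of A) over
  valid rays: a flat start whose forward projection has the data's scale.
* The continuous-time system is integrated in log-coordinates u = log x
  (du/dt = log f(e^u)) with LSODA at rtol 1e-6 / atol 1e-9: positivity
  holds by construction, matching the flow's invariance of the positive
  orthant, and the log-state is better conditioned near the small-pixel
  regime.
* FBP uses the classic Shepp–Logan discrete convolver
  h[k] = −2/(π²d²(4k²−1)) at the native detector spacing d, followed by
  pixel-driven linear-interpolation backprojection in the package's exact
  coordinate conventions, scaled by π/n_views. Negatives are not clipped.
  (Library FBP routines assume their own half-integer center conventions;
  reconstructing this package's sinograms with them shifts the image by
  half a pixel. They remain the cross-check in tests.)
* SSIM uses the reference defaults: Gaussian window σ = 1.5 truncated at
  radius 5 (the 11×11 tap filter), K1 = 0.01, K2 = 0.03, population
  statistics, data range 1.0 for [0, 1] phantoms, map cropped by the
  filter radius before averaging; it matches the standard library
  implementation to 1e-6.
* E(z) = ||e − z||₂ is reported **unnormalized** (no 1/J): its magnitude
  scales with the pixel count, and the benchmark tables only make sense on
  that convention.

## Experiment harness and problem sizes

`run_experiment` executes the checkpoint-table protocol (default: 128×128,
180×184, 30 dB, h = 1, MLEM to 200 iterations plus the matched members
(0.8, 1.2)@50, (0.5, 1.2)@100, (0.3, 1.2)@200) and prints E to two decimals
and SSIM to three, matching the conventional reporting precision.
`run_sweep` maps log10 E(z(N)) over a (γ, α) grid (default 15×15:
γ = 0.1…1.5, α = 0…1.4, step 0.1), reusing one cached system matrix and
one noise realization across all cells, and marks the MLEM point (1, 1) in
contour plots. One master seed drives a dedicated noise stream (the only
stochastic stage); reruns are byte-identical.

Problem sizes in the test suite are chosen for thoroughness per minute:
unit tests run at 8–16 px where dense oracles are exact; the
MLEM-equivalence check at 32 px; the Lyapunov/flow suite and the sweep at
64 px (90 views × 92 bins, the standard geometry halved); the noise-free
and noisy benchmark protocols at the full 128 px / 33,120-ray scale with
five noise seeds. The acceptance script always runs the full scale.

## Design choices that were genuinely open

* The benchmark's exact phantom densities are not published beyond "high
  contrast"; the canonical modified Shepp–Logan table is used, so
  benchmark comparisons carry a stochastic tolerance rather than printed-
  precision equality.
* The SNR convention (above) was selected as the reading consistent with
  the published benchmark behavior; both conventions ship.
* The projector's discretization (lines vs strips) is not fixed by the
  benchmark description; exact line lengths with diagonal detector
  coverage were chosen as the simplest deterministic, reproducible model
  consistent with 184 bins for a 128-px image (128·√2 ≈ 181).
* Whether the noisy contour maps share one noise realization across grid
  points is unstated; one shared realization is used, as a common-
  projection contour map implies.

## Known limitations

* Near the optimum γ the sweep's α-direction is nearly flat on noisy data
  (the 64-px sweep varies by ~2% along α at γ = 0.3), so the *exact*
  argmin location along α is seed-sensitive even though the small-γ
  preference is robust.
* At the earliest checkpoint (n = 50) the E-gap between MLEM and the
  (0.8, 1.2) member is within the uncertainty induced by the unspecified
  phantom/projector/SNR conventions (~3%), so its sign is not a robust
  property of this simulator even though the SSIM ordering and the later
  checkpoints' E orderings are.
* Fan-beam/cone-beam geometries, ordered-subsets acceleration, h > 1
  stability analysis, and regularized variants are out of scope.
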