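# Methods

This note records the models implemented in `reconqa`, the conventions and
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions made where the design was open.

## Conventions

* **Fourier transform.**  One convention project-wide (`reconqa.fourier`):
  DC at the array center, orthonormal scaling, both axes.  Unitarity means
  white noise keeps its variance between k-space and image space, which
  makes the g-factor algebra convention-free.
* **Complex Gaussian noise.**  Unit-variance complex noise carries
  variance 1/2 per real/imaginary component, so the coil covariance
  `Ψ = (1/n) N Nᴴ` (no mean subtraction; a centered variant is available
  behind a flag) is the complex covariance of the synthesized noise.
* **Coordinates.**  0-based, row-major.  Phase-encode lines are k-space
  columns; undersampling therefore spreads energy along the *horizontal*
  image direction.  All widths are in pixel units (isotropic spacing 1).

## Local point-spread functions

The LPSF at pixel `a` is the finite difference
`(T(O + b·e_a) − T(O)) / b`.  Choices:

* **Perturbation amplitude** `b` = 0.1 % of the maximum of the RSS image
  (`rel_amplitude = 0.001`).  `check_linearity` verifies, per operator and
  pixel, that the finite difference is amplitude-independent (default
  tolerance 5 %); for the TV-CS solver on the bundled fixtures the
  discrepancy between 0.1 % and 0.05 % amplitudes is ≈ 1 %.
* **Per-coil amplitudes** are proportional to each coil's signal at `a`
  (magnitudes summing in quadrature to `b`) with the phase of that coil's
  signal, held constant across experiments.  Pixels with zero signal fall
  back to uniform weighting with zero phase; such pixels are excluded from
  headline maps by the anatomy mask anyway.  A zero RSS image is an error.
* **Profiles** take the magnitude of the complex LPSF.  Magnitude is
  invariant to the global phase ambiguity of magnitude-output
  reconstructions; whether the real part would behave differently is
  untested here, and this is a deliberate, documented choice.
* **Threshold** is the analytic `2/π ≈ 0.6366` (the sinc amplitude half a
  pixel from its peak).  Rounded presentations of the same constant
  (64 %, 65 %) appear in the literature; the package uses the exact value.
* **Interpolation**: 5-fold zero-padded-spectrum (Fourier) interpolation
  of the profile before width measurement, with linear sub-sample
  refinement of the threshold crossings.  The residual granularity is
  visible as the ideal width measuring 0.990 rather than 1.000; the
  baseline tolerance is set at 2 %.
* **Peak search** is confined to ±(profile length / 4) around the
  perturbed pixel so that far-field response lobes (common for CS) cannot
  capture the peak.  Profiles that never cross the threshold on one side
  yield NaN and are flagged in `invalid_mask` rather than raised.
* `resolution_map` computes the unperturbed reconstruction once and
  shares it across pixels; results are independent of evaluation order.

## Pseudo multiple-replica g-factor

Each replica adds fresh `Ψ^{1/2}`-colored noise to every sample of the
full k-space grid, masks (accelerated arm only), reconstructs, and the
per-pixel sample std (ddof = 1) over replicas is taken on the final
real-valued magnitude images.  `g = σ_acc / (σ_normal √R)` with `R` the
mask's effective acceleration.

* `Ψ^{1/2}` is realized as the Cholesky factor; any factor `B` with
  `B Bᴴ = Ψ` yields the same noise law.
* Replica RNG streams are spawned from a seed sequence so the two arms and
  all replicas are independent yet reproducible.
* The std is computed on magnitude images because those are the images the
  maps describe.  At low SNR the magnitude is Rician and its std is biased
  low; the bundled fixtures keep signal ≫ noise (`noise_scale = 0.01`
  against order-1 images), where the magnitude std equals the std of the
  along-signal noise component, i.e. `sqrt(diag(AΨAᴴ)/2)` for a linear
  reconstruction `A` under the complex-variance convention above.  This
  closed form is the test oracle on a small grid.
* Default `n_replicas = 1000`; tests and the desk-scale studies use 250
  (2000 for the closed-form oracle) with Monte-Carlo-widened tolerances.
* Pixels whose reference std falls below `1e-3 ×` its median are flagged
  invalid instead of producing huge g values.

## Reference reconstructions

* **RSS-IFFT** (reference arm): per-coil inverse FFT, root-sum-of-squares
  combine.  **Zero-filled**: the same after masking — the baseline
  operator used in tests and examples.
* **GRAPPA.**  Missing phase-encode lines are filled per coil by a linear
  kernel over `kernel_kx` row neighbors × `kernel_sampled_lines` sampled
  lines of all coils, calibrated on the ACS region by Tikhonov-regularized
  least squares (weight = `tikhonov × trace(AᴴA)/n_features`; bumped 100×
  with a warning if the system is singular) and applied with circular
  boundary handling in both axes.  Calibration alignments are restricted
  to base lines on the R-grid anchored at line 0, mirroring the geometry
  the kernel is applied in.  Defaults `kernel_kx = 5`,
  `kernel_sampled_lines = 4`, `tikhonov = 1e-4` suit clinical matrix sizes
  (where an 8 % ACS spans ≈ 30 lines).  The bundled 128-line fixtures have
  a 10-line ACS, which cannot support a 4-sampled-line kernel at R = 4, so
  the fixtures calibrate a compact `(kx = 5, sampled_lines = 2)` kernel
  and use `tikhonov = 1e-6` because the fixture data is noiseless.
* **TV-regularized CS.**  `min_x ½‖M F S x − y‖² + λ·TV(x)` with isotropic
  TV on the complex image, solved by ADMM with a gradient split variable:
  CG x-updates (default 10 steps, warm-started), group soft-threshold
  z-updates, penalty `rho = 1`.  `λ = 0` falls back to a direct CG solve
  of the least-squares problem.  Returns magnitude; residuals and
  objective are available via `return_info`.  Fixture settings
  (`λ = 3e-3`, 50 iterations, 8 CG steps) were fixed once from a coarse
  λ grid scan on the noiseless phantom — chosen inside the flat region of
  the NRMSE curve, on the lighter-smoothing side of its minimum — since
  the regularization weight is inherently per-dataset.
* **Sensitivities** for the CS forward model can be estimated from the ACS
  (Hann-apodized low-resolution images normalized by their RSS, with
  below-threshold pixels masked).  The estimator is accurate with a wide
  ACS (≤ 5 % RSS-weighted error in tests); at the bundled 64-line matrix
  the 5-line ACS makes estimates poor enough to dominate the
  reconstruction error, so the desk-scale CS studies pass the generator's
  true maps instead and the estimator is validated separately.
* All operators return magnitude images and share one contract
  `(kspace, mask) -> image`, so external reconstructions (e.g. a learned
  model wrapped in a subprocess reading the HDF5 container and writing an
  image CSV) plug into the same resolution/g-factor machinery.

## Synthetic data

`make_phantom` rasterizes the classic 10-ellipse head phantom (or a
piecewise-constant block pattern suited to TV experiments) at pixel
centers; background is exactly zero, values are real and non-negative
with an optional smooth phase ramp.  `make_coil_sensitivities` places
Gaussian-profile coils on a ring (falloff `sigma_frac = 0.25` of the grid
— localized enough that an array provides genuine spatial encoding, which
R = 4 parallel imaging requires; near-uniform profiles would make the
problem ill-posed at any coil count) with smooth linear phases.
`make_noise_covariance` builds a unit-diagonal Hermitian matrix with
nearest-neighbor correlations (default magnitude 0.2) and random phases,
eigenvalue-floored if necessary.

What this does *not* emulate: realistic anatomy and contrast, 3D/multi-
slice or non-Cartesian acquisitions, coil geometries of a specific
scanner, B0/B1 inhomogeneity, and learned reconstructions.  Passing tests
on these fixtures show that the measurement machinery is correct and that
the classical methods reproduce their known signatures (GRAPPA: width ≈ 1
with g > 1; TV-CS: width > 1 in homogeneous regions, worst along the
undersampled direction, with g < 1); they do not predict the quantitative
widths or g values of any particular scanner/coil/anatomy combination,
which depend strongly on those factors.

## Problem sizes

The bundled studies run at desk scale: 128×128 / 8 coils for GRAPPA
(the smallest matrix whose 8 % ACS supports a calibratable kernel at
R = 4), 64×64 / 8 coils for TV-CS, 250 replicas for g-maps (2000 for the
8×8 closed-form oracle), and resolution maps on pixel subsets of a few
dozen points.  All choices are package defaults or explicit fixture
arguments and scale up directly.

## Known limitations

* Widths are 1D (horizontal/vertical) main-lobe widths; 2D lobe area or
  ellipse fits are out of scope, as are FWHM-based definitions.
* The sliding-window GRAPPA variant (calibration over all ACS alignments)
  is not implemented; aligned calibration needs an ACS a few kernel spans
  wide.
* `random_mask` selects lines uniformly (no variable-density weighting);
  Poisson-disc and partial-Fourier schemes are out of scope.
* The g-factor of strongly nonlinear methods depends on the noise level
  through the reconstruction itself; `noise_scale` is exposed and should
  be chosen to match the regime of interest.
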