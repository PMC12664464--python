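# reconqa

Spatially resolved, objective quality assessment of MRI reconstruction
methods: per-pixel **local point-spread-function (LPSF) resolution maps**
and **pseudo multiple-replica g-factor (noise amplification) maps**, for
any reconstruction that can be called as an operator on undersampled
multi-coil k-space.

Modern MRI reconstructions (parallel imaging, compressed sensing,
learned models) are nonlinear and shift-variant, so a single global
resolution or SNR number is not meaningful.  `reconqa` measures both
properties *locally*, pixel by pixel, treating the reconstruction as a
black box `T : k-space -> image`.  It ships everything needed to run the
analysis end-to-end with no scanner data: a multi-coil phantom simulator,
Cartesian undersampling masks, and reference reconstructions (RSS inverse
FFT, zero-filling, GRAPPA, TV-regularized compressed sensing via ADMM).

## The two measurements

**Local point-spread function.**  For a reconstruction operator `T`,
object `O`, and pixel `a`, the LPSF is the finite difference

```
LPSF(T, O, a) = (T(O + b·e_a) − T(O)) / b
```

with `e_a` a single-pixel impulse and `b` a small amplitude (0.1 % of the
maximum of the root-sum-of-squares image).  For small `b` this
approximates the differential of `T` at `O`, so it captures local blurring
of nonlinear methods.  Resolution is the width of the LPSF's main lobe at
`2/π ≈ 64 %` of its peak, measured on the horizontal or vertical profile
after 5-fold Fourier interpolation: for the fully sampled Fourier
reconstruction the LPSF is a sinc whose width at that threshold is exactly
one pixel (the Rayleigh limit — two points one pixel apart dip to
`8/π² ≈ 81 %` of the peak intensity between them).  Any width above 1 is a
loss of resolution.

**Pseudo multiple-replica g-factor.**  Receiver noise is complex Gaussian
and correlated across coils with covariance `Ψ = (1/n) N Nᴴ`, estimated
from an RF-free noise scan.  Synthetic replicas add noise colored by
`Ψ^{1/2}` to the k-space data; the per-pixel standard deviation over
replicas of the accelerated reconstruction, relative to the fully sampled
reference, gives

```
g(x, y) = σ_acc(x, y) / (σ_normal(x, y) · √R)
```

`g > 1` means the method amplifies noise beyond the unavoidable `√R`
penalty of the shortened scan; `g < 1` means it suppresses noise.

## Worked example

```python
import numpy as np
from reconqa import phantom as ph, sampling as sp, recon as rc, lpsf, gfactor as gf, report as rp

# synthetic 8-coil acquisition
phantom = ph.make_phantom(64, 64, "shepp_logan")
sens = ph.make_coil_sensitivities(8, 64, 64, "gaussian_ring")
cov = ph.make_noise_covariance(8, 0.2, seed=7)
kspace = ph.simulate_acquisition(phantom, sens, cov, noise_scale=0.0, seed=0)
coil_images = sens.maps * phantom.pixels

# resolution of the fully sampled reference at one pixel
pert = lpsf.build_perturbation(coil_images, (32, 32))
resp = lpsf.compute_lpsf(rc.rss_operator, coil_images, None, pert)
prof = lpsf.fourier_interpolate(lpsf.extract_profile(resp, "horizontal"), 5)
print(f"reference main-lobe width: {lpsf.mainlobe_width(prof):.3f} px")

# zero-filled R=4: resolution and g-factor
mask = sp.random_mask(64, R=4, acs_fraction=0.08, seed=1)
rmap = lpsf.resolution_map(rc.zero_filled_recon, coil_images, mask,
                           "horizontal", pixels=[(32, c) for c in range(28, 38)])
print(f"zero-filled R=4 widths: median {np.nanmedian(rmap.widths):.2f} px")

cfg = gf.ReplicaConfig(n_replicas=250, seed=5, noise_scale=0.01)
gmap = gf.gfactor_pipeline(rc.zero_filled_recon, kspace, mask, cov, cfg)
support = rp.anatomy_mask(rc.rss_ifft_recon(kspace), 0.05)
s = rp.summarize(gmap.g, support & ~gmap.invalid_mask)
print(f"zero-filled g-factor quartiles: {s.q25:.2f} / {s.q50:.2f} / {s.q75:.2f}")
```

prints

```
reference main-lobe width: 0.990 px
zero-filled R=4 widths: median 1.12 px
zero-filled g-factor quartiles: 0.24 / 0.25 / 0.26
```

The fully sampled reference sits at the one-pixel ideal (0.99, within the
granularity of 5-fold interpolation).  Zero-filling an R=4 random mask
blurs the undersampled direction (median width 1.12 px) and, because
dropping 75 % of the lines removes noise power without any reconstruction
to re-amplify it, its replica std sits far below the √R-scaled reference
(g ≈ 0.25 — zero-filling "suppresses" noise at the price of aliasing).
The same calls with `grappa_operator(...)` or `tv_cs_operator(...)`
reproduce the characteristic method signatures: GRAPPA holds width ≈ 1
everywhere but has g > 1, TV-CS blurs homogeneous regions (width > 1,
worse along the undersampled direction) while pushing g well below 1.

## Command line

Every stage is also exposed as a CLI for shell pipelines:

```bash
reconqa simulate --rows 64 --cols 64 --coils 8 --out scan.h5
reconqa mask --type random --lines 64 --r 4 --out mask.csv
reconqa recon --method cs --in scan.h5 --mask mask.csv --out img.csv
reconqa lpsf-map --method grappa --in scan.h5 --mask mask.csv --axis h --out wmap.csv
reconqa gfactor --method grappa --in scan.h5 --mask mask.csv --replicas 1000 --out gmap.csv
reconqa cfa --map gmap.csv --image img.csv --out curve.csv
```

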