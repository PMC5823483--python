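# subbandct

Fan-beam CT simulation and **subband-specific deconvolution reconstruction**
for uniform spatial resolution across the field of view.

## The problem

Spatial resolution in fan-beam CT is not uniform: the X-ray beam diverges as
it propagates, so a structure close to the tube is imaged through a wider
geometric blur than one close to the detector. Over a full rotation every
off-isocenter point is seen at a range of source distances, and the ordinary
filtered-backprojection (FBP) image ends up sharper at the isocenter than at
the periphery — which is why patient tables are routinely repositioned to put
the organ of interest at the rotation center.

`subbandct` implements an analytical fix that needs no hardware change.
Writing the equal-angle fan-beam FBP as

```
f(x, y) = ∫₀²π Σᵢ dᵢ L⁻² ∫ q(γ, β) h(γ′ − γ) D cos γ dγ dβ ,
```

each view's backprojection is partitioned into *n* annular subbands of
distance *L* from that view's source position, and every subband is passed
through a regularized Gaussian deconvolution `dᵢ` whose width follows a
rational model of source distance *x*:

```
σ(x) = (a x² + b x + c) / (d x + e) ,
```

fitted to Gaussian widths measured from thin-rod scans at a handful of known
offsets. With all widths zero, every `dᵢ` is the identity and the formula
*is* ordinary FBP. Because the source rotates, each pixel accumulates a
position-dependent superposition of deconvolution kernels — wider where it
was near the tube — which equalizes the modulation transfer function (MTF)
across the FOV. The default operating point is **n = 11 subbands**, a balance
between resolution recovery and noise boost.

The package contains everything needed to demonstrate this end to end with
no external data: parametric phantoms (rods, bar groups, a lung-like
layout), an exact analytic fan-beam projector with a distance-dependent blur
model and Poisson noise, equal-angle Ram-Lak FBP plus an unsharp-masking
"sharpened FBP" comparator, rod-based PSF estimation, the kernel-width model
fit, the subband reconstruction itself, and two MTF estimators
(Fourier/point method and the standard-deviation bar-group method) with a
resolution-uniformity report.

## Worked example

`examples/04_mtf_uniformity_report.py` runs the whole pipeline at desk
scale: bar phantoms at 6, 47 and 127 mm from the isocenter, acquired through
the geometric-unsharpness blur model and reconstructed three ways. It
prints:

```
MTF at 5 lp/cm per offset (noiseless battery):
  fbp            6 mm: 0.174     47 mm: 0.178    127 mm: 0.209   spread 0.189
  sharp_fbp      6 mm: 0.325     47 mm: 0.331    127 mm: 0.388   spread 0.183
  subband        6 mm: 0.678     47 mm: 0.665    127 mm: 0.632   spread 0.069

subband spread / fbp spread = 0.36 (smaller means more uniform resolution across the FOV)
```

Reading the numbers: plain FBP transfers only ~18% of the 5 lp/cm bar
modulation and varies by ~19% across the FOV; unsharp masking boosts the
level but — being a fixed shift-invariant filter — cannot touch the
*relative* variation; the 11-subband deconvolution restores the MTF to
~0.65 everywhere and cuts the spread, (max − min)/mean, to 0.07. The other
examples show the individual stages: simulation + FBP (`01`), rod-based PSF
measurement and the σ(x) model fit (`02`), and the subband reconstruction
with its exact zero-width reduction to FBP (`03`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the uniformity battery from scratch — simulating the blurred,
noisy acquisitions, fitting the kernel-width model, reconstructing with all
three methods and measuring the bar-pattern MTF per offset — prints the
per-method uniformity summary, and writes the results JSON to `--out`.

## Layout

| path | contents |
| --- | --- |
| `src/subbandct/geometry.py` | fan-beam geometry, reconstruction grid |
| `src/subbandct/phantoms.py` | primitives, phantom builders, rasterization, exact ray integrals |
| `src/subbandct/projector.py` | analytic projector, distance-dependent blur, Poisson noise |
| `src/subbandct/fbp.py` | equal-angle Ram-Lak FBP, sharpened-FBP comparator |
| `src/subbandct/psf.py` | rod-σ estimation, kernel-width model, subband partition |
| `src/subbandct/subband.py` | regularized deconvolution, subband reconstruction |
| `src/subbandct/mtf.py` | MTF estimators, uniformity report |
| `src/subbandct/pipeline.py` | end-to-end battery helpers |
| `docs/methods.md` | model, assumptions, parameter choices, limitations |
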