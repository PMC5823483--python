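# Methods

This note documents the models implemented in `subbandct`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not establish.

## Geometry and conventions

Equal-angle (arc-detector) fan-beam geometry over a full 2π rotation.
Isocenter at the origin, millimetres throughout; the +y axis points toward
the β = 0 source position and β increases counter-clockwise. A signed
phantom offset is positive toward the detector of the β = 0 view (i.e.
*away* from the source); a `flip_sign` flag reverses this, since real
measurement protocols rarely state their sign convention. Channel angles are
γ_c = (c − (n−1)/2)·Δγ with Δγ = pitch/SDD; the FOV is the disk of radius
R = D·sin(γ_m).

Default distances D = 600 mm, SDD = 1100 mm are stand-ins typical of
diagnostic CT scanners — the emulated system's true distances are not
public. Detector defaults (912 cells of 1.09 mm, 1440 views) match the
emulated scanner's published layout; the test battery scales them down (see
below).

## Forward model

The projector is analytic: disks, ellipses and bars (rectangles) have
closed-form chord lengths, so the ideal sinogram carries no discretization
error. Phantom elements carry *signed additive* attenuation contrast; this
deviates from a per-element non-negativity rule because nested anatomy (low
attenuation lung fields inside a body ellipse) is not expressible in a
purely additive non-negative model. The composite rasterized map is
validated non-negative instead.

Distance-dependent blur emulates geometric unsharpness. With an effective
focal spot F, a point at source distance x is blurred (in object space) by

    σ_obj(x) = F·(SDD − x)/SDD      [mm]

— wider near the tube, and equivalent to σ_obj/(Δγ·x) detector channels.
The simulator default is F = 1.2 mm, a realistic large focal spot, chosen
once so that mid-frequency bar patterns (5 lp/cm) sit on the steep part of
the MTF at the default geometry. The blur is applied along the
detector-channel axis only (divergence acts across the beam), per view, by
splitting the phantom into depth bands: each primitive's exact projection is
distributed over bands in proportion to its area per band, each band is
convolved with its Gaussian (zero-padded detector boundary), and the bands
are summed. The area-fraction split keeps the decomposition an exact
partition (unblurred bands sum to the ideal projection to machine
precision); its cost is that a primitive straddling a boundary contributes a
slightly blur-averaged rather than geometrically split profile, negligible
for the small structures used here. Whether a real system's divergence blur
is best modelled in channel or image space is not observable at this level;
channel space is the explicit modelling decision.

Noise is monoenergetic Poisson counting noise on N·exp(−p) photons per ray;
zero-count rays are clamped to log(N) and logged.

## Reconstruction

`fbp` implements the standard equal-angle fan-beam FBP: channel weighting by
D·cos γ, convolution with the discrete fan-modified Ram-Lak kernel
(g[0] = 1/(8Δγ²), g[odd n] = −1/(2π² sin²(nΔγ)), zero otherwise), and
L⁻²-weighted backprojection with linear interpolation at γ′; channels beyond
±γ_m contribute zero and pixels outside the FOV disk are zeroed. The
truncated kernel keeps a small DC residue, which is removed by subtracting
the tap mean — a flat (post-weighting) view then filters to ~0. Full-scan
(2π) only; no short-scan weighting. "Sharpened FBP" — a comparator whose
exact construction is unspecified in the source measurements it emulates —
is realized as unsharp masking, out = img + amount·(img − G(img)), defaults
amount 1.0, radius 2 px. Being shift-invariant, it scales the MTF by a fixed
frequency response and therefore cannot change *relative* resolution
uniformity; that is exactly its role as a control.

## PSF measurement and the kernel-width model

A 1 mm rod scanned alone at a known offset gives, per view, a detector
profile that is the ideal rod projection convolved with the system blur.
Views within ±60° of the reference view are used (there the rod's source
distance is ≈ D + offset, keeping the five signed offsets at five distinct
distances); per view a Gaussian is fit to the profile, the ideal rod
projection's Gaussian-equivalent width (matched second moment, r/2 at the
rod) is removed in quadrature, and views are aggregated by the median, which
is robust to edge-of-fan views. When the profile spans fewer than five
channels a three-parameter Gaussian fit is underdetermined; the estimator
falls back to the second moment and pairs it with the moment of the
*discretely sampled* ideal profile at the same sub-channel phase, which
cancels the sampling-phase bias (an unblurred rod then reports ≈ 0 rather
than a spurious half-channel width).

Widths measured in channel units convert to reconstruction pixels by
σ_px = σ_ch·Δγ·x/p, because the deconvolution operates in image space. The
rational model σ(x) = (ax² + bx + c)/(dx + e) is linear and homogeneous in
its coefficients once multiplied out, so a gauge must be fixed:

* `e_fixed_1` — set e = 1, least squares for (a, b, c, d);
* `unit_norm` — smallest right singular vector of the 5-column system;
* `polynomial` — d = 0, e = 1 (a plain quadratic, still in the family).

Both free-denominator gauges agree to machine precision whenever the data
are exactly representable. With *noisy* measurements, however, the
free-denominator least squares can interpolate through a pole inside the
FOV range (classic rational overfitting); the fit validates positivity and
a non-vanishing denominator over its stated valid range and refuses such
models, naming the crossing point. The `polynomial` gauge is the pole-free
fallback and is the right choice when the width–distance relation is close
to linear, as it is for pure geometric unsharpness in pixel units. Five
pairs determine the four gauge-fixed unknowns with one residual degree of
freedom; more rods give a smoother overdetermined fit.

The package ships one scanner-derived fixture (five widths 0.1–1.1 measured
with aluminium rods at 0, ±7, ±14 cm on a clinical system). Its printed
pairing is non-monotonic in source distance — opposite to the geometric
argument — and under either free gauge the exact rational solve develops a
pole in the middle of the FOV, for either pairing interpretation. The
fixture therefore serves as a realistic cautionary input: the fit reports
the pole per contract, and no quantitative result in this package depends
on it.

## Subband partition and reconstruction

The FOV's source-distance range [D − R, D + R] is split into n equal-width
bands (default n = 11); each band's representative σ is the model evaluated
at the band center. Equal-width edges are the simplest defensible choice;
equal-population or per-view adaptive edges are plausible alternatives not
explored. Per view, every FOV pixel is assigned to the band containing its
distance L to that view's source; the masks are pairwise disjoint and cover
exactly the FOV disk, and the isocenter pixel's band never changes (L = D
for every view).

Each view's backprojection is deconvolved once per band — *whole image*
deconvolution followed by masking, which avoids the hard-edge ringing of
deconvolving cropped regions — and the masked results are summed and
accumulated over views. Deconvolution is constrained least squares in the
frequency domain, f̂ = conj(Ĥ)·ĝ/(|Ĥ|² + λ|L̂|²) with L the 5-point
Laplacian, computed after symmetric padding; the DC gain is exactly 1, so
flat regions and the image mean are preserved. The kernels are isotropic
2-D Gaussians: the physical blur is directional, but the measured PSFs are
summarized as isotropic Gaussian fits and the deconvolution mirrors that.
Deconvolution happens in the backprojection domain (the method's defining
equation); a sinogram-domain variant is deliberately not implemented.

Numerical parameters: λ = 1e-3 by default (the emulated workflow's
regularization strength is unpublished; λ is exposed and recorded in
provenance), Gaussian support truncated at 4σ, bands with σ < 0.3 px passed
through unmodified (sub-pixel kernels amplify discretization noise for no
resolution benefit), hard masks by default with an optional cosine-taper
partition of unity ("feather") across band edges. Per-band frequency
responses are precomputed once per reconstruction — the kernel depends on
the band, not the view — making the cost one forward and ~n inverse FFTs
per view.

Properties verified by the test suite: the zero-width model reproduces FBP
to machine precision for any n; a single band collapses to one global
deconvolution; the whole chain is linear in the sinogram; image noise rises
monotonically as λ shrinks (the noise-boost trade-off that motivates a
moderate band count).

## MTF measurement

* **Fourier/point method**: background-subtracted ROI around an isolated
  object, radially averaged FFT modulus, divided by the ideal object's
  spectrum (2J₁(πdf)/(πdf) for a disk of diameter d), normalized to 1 at
  DC. Validated against the closed form exp(−2π²σ²f²) for Gaussian PSFs to
  within 3% up to 0.25 cycles/pixel.
* **Bar-group (standard-deviation) method**: MTF(f) =
  (π√2/4)·√(Var_bars − Var_noise)/(ΔCT/2), with the material means taken
  from uniform companion ROIs and the noise variance from a matched uniform
  ROI. A perfectly resolved square wave reads π√2/4 ≈ 1.11 — supra-unity by
  construction, since the constant refers the standard deviation to the
  square wave's fundamental. Validated against a first-harmonic Fourier
  oracle on synthetic sinusoids to within 2%.

Curves are labelled primarily in cycles/pixel with lp/cm as the secondary
axis (lp/cm = 10·cycles/pixel/pixel_mm). The uniformity report tabulates
the MTF at a stated frequency across offsets, normalizes by the smallest
offset, and summarizes with the spread (max − min)/mean; the normalized
series is invariant under global rescaling of the reconstruction.

## The scaled-down uniformity battery

The demonstration experiment runs on one CPU in ≈ 1–2 minutes: detector
reduced to 476 channels (FOV radius ≈ 140 mm, still covering a 127 mm
offset), 360 views, a 512 px / 0.55 mm grid, bar groups at 5 lp/cm, and the
geometric blur model above. Two deliberate departures from a full-scale
protocol: a grid that covers the whole FOV cannot simultaneously sample a
10 lp/cm pattern at this budget, so the battery measures at 5 lp/cm; and
the reconstruction grid is finer (0.55 mm) than a standard 512-grid body
protocol so the bar period spans ≈ 3.6 px. The battery's claims are
comparative (subband vs. FBP vs. sharpened FBP on identical data), so the
frequency choice affects the operating point, not the logic of the
comparison.

What a green battery establishes: under a known, smoothly varying,
Gaussian, channel-axis blur, the subband reconstruction restores
mid-frequency MTF well above FBP at the FOV periphery and holds it more
uniform across offsets than either comparator. What it does not establish:
performance under real focal-spot shapes, detector cross-talk, scatter,
polychromatic physics, 3-D (cone/helical) geometry, or mismatch between the
fitted width model and the true PSF field beyond the measurement noise the
rod pipeline introduces.

## Known limitations

* 2-D axial, full-scan, equal-angle geometry only; no flat detector, no
  short scan, no iterative reconstruction.
* The blur model is a single Gaussian width per depth band; no angular
  subdivision of bands (a flagged possible refinement).
* The rod-σ estimator assumes one rod per sinogram and known rod geometry;
  overlapping objects or unknown diameters are out of scope.
* Rational-model fits from few noisy points are fragile by nature; the
  package surfaces poles as errors rather than silently clamping, and the
  polynomial gauge is the practical fallback.
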