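# Methods

## Forward model

**Skin optics.** Skin is modeled as two layers. The epidermis is a pure
absorption layer: melanin with volume fraction `f_mel ∈ [0.013, 0.43]`
gives Beer–Lambert transmittance `T(λ) = exp(−f_mel ε_mel(λ) d_epi)`;
scattering there is neglected (the layer is thin). The dermis is a
semi-infinite absorbing–scattering half-space: hemoglobin with blood
volume fraction `f_hb ∈ [0.02, 0.07]` sets `μ_a(λ) = f_hb ε_blood(λ)`,
collagen/elastin set the reduced scattering
`μ_s′(λ) = a (f_Ray (λ/λ₀)⁻⁴ + (1−f_Ray)(λ/λ₀)^(−b_Mie))`. Total
reflectance composes as `R = T² R_dermis`, light crossing the epidermis
twice. `R_dermis` uses the standard diffusion-approximation closed form
for a semi-infinite medium,

```
R_d = a′ / (1 + 2k(1−a′) + (1 + 2k/3)·sqrt(3(1−a′))),    a′ = μ_s′/(μ_a+μ_s′),
```

with internal-reflection parameter `k` from the Groenhuis polynomial for
relative refractive index 1.4. This form depends on the absorption/
scattering ratio only, equals 1 for a lossless half-space and decreases
monotonically with absorption — the properties the pipeline relies on.

**Image formation.** Per channel, `I_m = shading · ∫ L R C_m dλ +
specular · l_m` over 450–750 nm (5 nm default step, trapezoidal
quadrature), where `l_m = ∫ L C_m dλ` is the response to the bare source.
Shading and specular are wavelength-independent per-pixel scalars. The SPD
is normalized so the most sensitive channel has `l_m = 1`. White balance
divides by `l_m`; a camera→XYZ matrix is least-squares fitted on a
simulated 24-patch chart (the "virtual ColorChecker"), with the XYZ
targets von-Kries-adapted channelwise so the profile's own illuminant
lands exactly on the sRGB/D65 working white (rank-deficient charts, e.g.
a grays-only chart, fall back to the minimum-norm solution, which still
maps grays to grays); then the standard XYZ→linear-sRGB matrix and the
pure power-law gamma `I_srgb = 1.055 I^(1/2.4) − 0.055` (no linear toe
segment; encode output clipped to [0, 1], decode is its exact algebraic
inverse pre-clip).

**Rendering LUT.** Spectral quadrature per pixel per training step is
wasteful, so the diffuse working-RGB color per unit shading is
precomputed on a 97×49 `(f_mel, f_hb)` lattice through the exact spectral
path and queried bilinearly; agreement with the exact path is below
1e−3 (tested), and the analytic gradients of the bilinear lookup make the
renderer differentiable. The same LUT also yields the **pixelwise
inverse**: with zero specular, diffuse chromaticity `(R/S, G/S)` is
shading-independent and maps one-to-one onto `(f_mel, f_hb)`; shading is
the remaining magnitude ratio. This inverse is exact on noise-free
diffuse pixels (tested against random states).

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `d_epi` | 0.006 | cm | typical epidermal optical path scale |
| blood oxygenation | 0.70 | — | fixed oxy/deoxy mixture for the blood spectrum |
| `a` | 45 | cm⁻¹ | skin reduced scattering at λ₀ (literature family) |
| `b_Mie`, `f_Ray`, `λ₀` | 1.3, 0.4, 500 nm | — | Rayleigh+Mie mixture for dermis |
| band, step | 450–750, 5 | nm | integration band of the formation integral |
| patch, overlap | 256, 15 | px | tiling geometry; 4×6 grid ⇒ 979×1461 px |

All are configuration, not claims about any particular instrument.

**Bundled spectra** (`src/chromodecomp/data/`, regenerated by
`scripts/make_bundled_spectra.py`) are analytic stand-ins, not
measurements: melanin follows the standard melanosome power law
`6.6·10¹¹ λ^−3.33` cm⁻¹ per unit fraction; oxy/deoxy hemoglobin are
monotone-spline interpolations through approximate anchor values of the
standard compiled molar-extinction tables, converted to whole-blood
absorption at 150 g/L; the illuminant is a Planckian 6504 K daylight
approximation; the CIE 1931 2° observer uses the published multi-lobe
Gaussian analytic fit; camera sensitivities are synthetic DSLR-like
Gaussian passbands; the ColorChecker is a synthetic 24-patch chart (6
neutrals + 18 smooth chromatic spectra). Every curve is swappable via the
CSV/profile-bundle interface.

## Decomposition network and training

A reduced-channel U-Net (default 4 pooling stages, base width 16;
the desk-scale benchmark uses 3 stages, width 12) maps a patch to four
sigmoid-bounded channels, affinely mapped onto melanin [0.013, 0.43],
hemoglobin [0.02, 0.07], shading [0, 2], specular [0, 1] — predictions
are inside the physiological box by construction. The network input is
the gamma-encoded patch plus the three range-normalized channels of the
analytic pixelwise inverse; the public contract takes working-linear
patches, featurization is internal. No deep-learning framework is used:
convolutions, pooling, upsampling and the U-Net forward/backward are
hand-written numpy (im2col + BLAS), every backward pass checked against
finite differences in the test suite; Adam with l2 weight decay and
cosine annealing drives the updates, fully reproducible from one seed.

**Loss.** The data term is the mean squared reconstruction error over
skin pixels, compared by default in gamma-encoded (sRGB) units — the
units of the original photograph. Linear-space comparison is available
(`loss_space="linear"`) but down-weights the dark green/blue channels
roughly threefold, which in practice starves the hemoglobin head of
gradient.

**Identifiability and priors.** Per pixel the rendered RGB has three
degrees of freedom while the maps have four; even with specular fixed at
zero the Jacobian with respect to (melanin, hemoglobin, shading) is
ill-conditioned (smallest singular direction ≈ 30× below the largest,
mixing the three maps). Reconstruction error therefore pins two map
combinations strongly and one weakly: a network can reconstruct at
35–40 dB while the weakly-pinned mixture — mostly hemoglobin — drifts
arbitrarily. At the training scales this package targets (minutes on one
CPU, not thousands of GPU epochs), the objective is regularized by four
configurable priors, all acting on the gradient only (the reported loss
stays the pure data MSE):

* specular l2 (default 0.01): cross-polarized acquisition suppresses
  surface reflection, so the specular head should be sparse;
* shading smoothness, |∇|² (default 0.3): shading encodes low-frequency
  geometry;
* chromophore smoothness, |∇|² on melanin and hemoglobin (default 3.0):
  tissue fields are spatially smooth, and the prior makes the network
  average sensor noise instead of reproducing it;
* physics anchor (default 0.3): quadratic pull of the melanin/
  hemoglobin/shading heads toward the analytic pixelwise inverse, in
  normalized units. This is the term that pins the weakly-identified
  mixture; the network then refines the (noisy, specular-corrupted)
  per-pixel estimate using spatial context.

With priors off the package reproduces plain self-supervised behavior:
reconstruction PSNR rises the same way, but chromophore recovery needs
far longer schedules than the desk-scale budget.

## Synthetic scenes

The generator emulates cross-polarized clinical photographs: melanin and
hemoglobin fields are Gaussian random fields (correlation length 16 px)
min–max squashed into sub-physiological ranges (0.03–0.28 and
0.025–0.065) with optional pigmented spots and vascular blobs; shading is
the Lambertian shading of a frame-covering ellipsoid scaled into
[0.55, 0.98]; speculars are sparse small Gaussian highlights; non-skin
background is an out-of-model blue-gray with low-frequency texture, and
two elliptical "eye" holes puncture the face mask. Rendering goes through
the same LUT forward chain as reconstruction (so ground-truth maps
reproduce the image exactly at zero noise), then additive Gaussian sensor
noise (σ = 0.002, linear domain) and gamma encoding. Scenes are
bit-reproducible from their seed; datasets are written as 8-bit sRGB
PNGs, 0/255 masks, 16-bit quantized truth maps plus an exact float
container, with a manifest CSV of per-scene seeds and statistics.

What the generator does *not* model: facial geometry and landmarks,
demosaicing and camera noise structure, inter-subject pigment statistics,
makeup, hair. Passing the recovery benchmarks therefore shows the
pipeline inverts *its own physics* under realistic noise — not that it
matches clinical analyzers on real faces, which would require the
calibration study the underlying approach anticipates.

## Benchmark problem sizes

The desk-scale replication (`chromodecomp.benchmark`) trains the reduced
U-Net (width 12, depth 3) on 200 synthetic 256×256 patches — random
64-pixel crops, flips and right-angle rotations, batch 4, 60 epochs,
Adam 1e−3 with cosine annealing to 1e−5 — and evaluates 20 held-out
patches: mean reconstruction PSNR (sRGB units, skin pixels) and Pearson
correlation of predicted vs. true melanin and hemoglobin maps. The
segmentation model trains on synthetic scenes with exact masks at a
reduced working resolution in the tests; its published-scale working
resolution (640×480) is the default for real use.

## Numerical choices, degenerate inputs

Spectral curves validate strict wavelength monotonicity and finiteness;
off-grid queries interpolate linearly and out-of-band queries raise.
Gray-scale visualization min–max scales over skin pixels and raises on
constant maps; Pearson correlation raises on zero variance; white balance
and profile normalization raise on non-positive white responses; the
dermis formula rejects zero scattering. Combining a patch set verifies
completeness; blend ramps use weights i/(o+1) so complementary ramps sum
to one exactly. PSNR is capped at 100 dB for identical images. Edits in
the simulator re-clamp to the physiological box before rendering.

## Known limitations

* Recovery quality rests on the smoothness and anchor priors at this
  compute scale; structures sharper than the priors allow (fine vascular
  detail) are smoothed.
* The bundled spectra are analytic approximations; absolute fraction
  values are model-relative, not calibrated measurements.
* The gamma transfer is the pure power law, not piecewise sRGB; images
  from other pipelines should be linearized accordingly.
* Specular highlights corrupt the pixelwise inverse locally; the network
  compensates only partially.
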