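# Methods

This note documents the models, estimators, parameter choices, and known
limits of `octoprops`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Forward model and digital phantoms

The simulator (`octoprops.phantom`) generates OCT intensity volumes from
voxel maps of the attenuation coefficient μ (mm⁻¹) and the relative
backscattering coefficient β (dimensionless, in units of the reference
medium's backscatter). The speckle-free mean intensity is

    I(x, y, z) = β(x, y, z) · exp(−2 A(x, y, z)) · h(z),
    A(x, y, z) = ∫₀ᶻ μ(x, y, z′) dz′,

with the system constant fixed to 1: the estimators only ever consume
ratios of volumes, so absolute radiometry is deliberately out of the
model. The depth integral is discretized as a cumulative sum over voxel
centres with a half-voxel offset, A(z_k) = Δz·(Σ_{j≤k} μ_j − μ_k/2),
which makes the noiseless log-intensity slope on a homogeneous block
equal −2μ *exactly*, not just asymptotically; the test suite checks the
whole forward model against an independent per-voxel loop at machine
precision.

**Confocal profile.** `h(z) = 1/(1 + ((z − z_f)/z_R)²)`, the axial
collection efficiency of a focused Gaussian beam with focus depth `z_f`
and Rayleigh range `z_R`, or `h ≡ 1`. Because sample and reference share
the profile, it cancels in the normalization; the tests assert exact
cancellation.

**Speckle.** Fully developed speckle is modelled as i.i.d. unit-mean
exponential intensity multipliers — the standard statistics of coherent
imaging of many sub-resolution scatterers, and the default for every
validation study in this package. A `correlated_field` variant draws a
complex circular-Gaussian field, smooths it to requested correlation
radii with periodic boundaries (so the unit-mean rescaling is exact
everywhere), and takes the squared magnitude; it exists for realism
studies of finite speckle grains. The noise floor is additive unit-mean
exponential intensity scaled by the floor level (intensity statistics,
not field statistics).

What the generator does *not* emulate: multiple scattering, angle
dependent phase functions, refraction at interfaces, depth-dependent
axial resolution, k-linearization or dispersion artefacts, and motion.
Passing tests therefore demonstrate correctness of the estimators under
single-scattering Lambert–Beer contrast with speckle — not robustness to
every artefact of a physical instrument.

## Reference normalization

Each sample A-line is divided by a homogeneous reference acquisition
(`normalize_to_reference`). The default collapses the reference to its
lateral-mean A-line profile first — with ~10⁴ A-lines the profile's
speckle noise is negligible and the division does not add noise; a
`voxelwise` mode exists for identical-grid ratio tests. Voxels at or
below the instrument noise floor are masked, excluded downstream, and
replaced by their z-plane median before filtering so that ratio blow-ups
cannot contaminate neighbours through the filter support.

## The Gabor filter bank

The bank is a separable Gaussian envelope times complex axial carriers.
The envelope is parameterized by its **1/e² radii** (Δx, Δy, Δz) — the
distance at which the envelope falls to e⁻² — so σ = radius/2; defaults
are Δx = Δy = 20.0 μm, Δz = 6.1 μm (σ_z = 3.05 μm). Kernels are
truncated at 4σ and normalized per axis to unit sum, which fixes the
zero-frequency DC gain at exactly 1 (asserted to 1e−12): a constant
ratio c maps to β̂ = c.

Frequencies: `n_freqs = 7` samples uniformly spanning [−F, F] with
F = 1/(2π σ_z) by default. At that span the Gaussian spectral magnitude
stays at or above e^(−1/2) of its DC value, keeping the phase samples
well conditioned; the span is validated against the axial Nyquist limit.

Implementation is demodulate → separable Gaussian smooth → remodulate.
Boundary rule: the *data* is reflected (edge-including symmetric
reflection on all axes) while the demodulation carrier continues
linearly across the z pad. Reflecting the demodulated product would
mirror its phase and corrupt phase slopes near the z boundaries; with
the linear carrier a constant ratio yields exactly zero phase at every
voxel, including edges. The filter equals an independent brute-force
windowed DFT (same truncation, same reflection) to better than 1e−6
relative on random volumes. A 3σ boundary margin is masked as invalid in
all outputs.

## Attenuation from the phase slope

For a locally exponential ratio r ~ exp(−a z), the Gaussian-windowed
spectrum is ∝ exp(σ_z²(a + 2πif)²/2), so

    arg G(f) = 2π σ_z² a f.

Per voxel the phases are unwrapped along f (a guard against pathological
inputs; at physiological μ·σ_z the phases are ~10⁻³ rad) and fitted by
|G|-weighted least squares; a two-point finite-difference mode across
±Δf is retained for comparison and agrees with the weighted fit on clean
exponentials. The slope gives a = 2(μ_s − μ_r) and the normalized AC
μ̂ = (μ_r + a/2)/μ_r, so the reference medium maps to μ̂ = 1; a
`difference` mode returns μ_s − μ_r in mm⁻¹. Noiseless closed-form
recovery is ≤0.1%. Voxels with fewer than three usable frequencies are
masked, not errored.

## Backscatter from the zero-frequency magnitude

|G(0)| is the windowed local mean of the ratio: the local backscatter
level times the *accumulated* residual attenuation
exp(−2∫(μ_s − μ_r)dz′). `estimate_bsc` undoes the accumulation with the
estimated AC map, integrated along each A-line with the same half-voxel
rule as the forward model, then removes the (analytically exact for
locally constant attenuation, numerically ~10⁻⁶ here) Gaussian window
bias exp(σ_z² a²/2).

Two safeguards matter in practice:

* **Axial-margin replication.** The AC map inside the 3σ axial boundary
  margin is invalid; integrating through it would poison every deeper
  voxel (a 34% systematic in early testing). The margin is replaced by
  the nearest valid value before integrating.
* **Outlier rejection in the integrand.** At a sharp backscatter step of
  ratio q the phase slope reads an apparent attenuation whose integral
  is −ln(q)/2 — integrating it would cancel exactly the β contrast being
  mapped (a 10× step collapsed to ~1× before this fix). Voxel values
  outside median ± `compensation_halfwidth`·μ_r (default halfwidth 1.0)
  are replaced by the average of the nearest axial inliers. The window
  is symmetric about the bulk value, so homogeneous regions — where the
  voxel-wise Δμ̂ noise under speckle is itself ~1 mm⁻¹ — are not biased;
  flat layered phantoms recover β to ~1% under speckle.

This regularization reflects a genuine identifiability limit: a
*gradual* axial change of β is indistinguishable from attenuation for
any estimator based on local axial decay. The practical consequence is
visible on spherical inclusions: where A-lines cross the surface at
grazing incidence (the equator of a spheroid), the β step is smeared
along z and partially absorbed into the attenuation estimate, biasing β̂
low by ~10% locally even without noise. Region statistics near steep
incidence (poles, interiors) are unaffected; the test suite encodes this
by checking strict parameter recovery on flat-layered geometry and on
spheroid interiors, and ordering/contrast on full spheroids.

## Baseline estimators

For the precision comparison the package includes first-principles
implementations of the two conventional readouts, both per-A-line (no
lateral averaging) and both configured to the same effective axial
support as the Gaussian window (equivalent boxcar length 2√π σ_z):

* **LF (log-and-fitting):** OLS slope of ln r versus depth over a
  centred boxcar window; Δμ = −slope/2. Exact on noiseless
  exponentials.
* **FD (Fourier-domain):** boxcar-windowed axial Fourier transform with
  the same phase-slope readout as the Gabor core. The transform is
  sampled at fractional frequencies spanning ±√12/(2πT) rather than
  integer DFT bins — a boxcar of length T is orthogonal to its integer
  bins for slowly varying signals, leaving only ±π/2 carrier phases, so
  the bin readout carries no attenuation information. The slope-to-rate
  constant is calibrated once against a noiseless exponential
  (calibration by construction); residual nonlinearity across the
  physiological range is <0.5%.

On speckled homogeneous phantoms the voxel-wise spread orders
std(Gabor) < std(FD) < std(LF), per-seed in ≥80% of 20 seeds (checked);
the fold-change between methods depends on instrument and window
configuration and is not asserted.

## Validation protocols and desk-scale statistics

`octoprops.validation` fixes two reference studies:

* **Phantom accuracy** (`phantom_accuracy_study`, also the acceptance
  script): homogeneous phantoms at normalized (AC, BSC) levels
  (0.4, 0.09), (0.5, 0.15), (0.6, 0.12), (0.8, 0.20) — spanning the
  range reported for untreated→treated spheroids against a μ_r =
  1.0 mm⁻¹ reference — at 128×128×512 voxels, (1.0, 1.0, 0.61) μm
  pitch, fully developed speckle, matched simulated reference, default
  bank. The phantom-level estimate is the mean of the voxel map over the
  valid interior; the score is the mean absolute relative error over 12
  seeded realizations. For a homogeneous phantom this volume-level
  aggregation is the quantity of interest (one AC and one BSC per
  phantom), mirroring how a concentration series is scored per
  concentration.
* **Backscatter ladder** (`bsc_ladder_study`): media at 0.5–5× the
  reference concentration (μ and β both scaled), scored for
  per-concentration volume-level CV and for linearity (R²) of mean β̂
  against truth.

A statistical point documented here because it bounds what desk-scale
simulation can show: the phase carries ~2πσ_z²aF ≈ 10⁻³ rad of
attenuation signal across the band, while fully developed speckle leaves
~N_eff^(−1/2) rad of phase noise per voxel (N_eff ≈ voxels under the
window). Volume-level AC noise therefore scales as ~1/√N_total and is
≈1–1.6% at 128×128×512 — that, not estimator bias (≤0.1% noiseless), is
the AC error floor at this size. The same estimator on a full
500×500×4096 acquisition (~120× more voxels) has a floor of ~0.1%.
Backscatter is far better conditioned (|G(0)| averages intensity
linearly), so its desk-scale error is ≈0.8%. Voxel-wise AC error under
speckle is ~100% at a 6.1 μm window by the same arithmetic — the
per-voxel map is meaningful after regional aggregation, which is how it
is used. Relatedly, the *volume-mean* precision is nearly independent of
the lateral window radii (the smoothing is inside the mean), while the
voxel-wise precision improves with them; the test suite asserts the
voxel-wise ordering over Δx = Δy ∈ {10, 20, 40} μm.

## Spheroid quantification

Segmentation is Otsu's threshold on log intensity, morphological closing
(ball, 2 voxels), largest connected component, hole filling; all
parameters are recorded on the mask. Morphometrics: volume by voxel
counting; height as occupied axial extent; diameter as the maximum Feret
diameter of the largest-area horizontal slice (equivalent-sphere
diameter also reported); Wadell sphericity π^(1/3)(6V)^(2/3)/A with the
surface area from a marching-cubes mesh of the lightly smoothed mask
(smoothing removes the ~7% staircase inflation of binary meshes; a
digitized ball scores ≥0.97, a 3:1 prolate ellipsoid 0.846 matching the
closed form); projected 2D circularity 4πA/P² from the marching-squares
contour polygon. Radial profiles bin voxels by normalized boundary
distance 1 − EDT/EDT_max (exactly r/R on a sphere, well defined on any
shape), averaging each shell over voxels valid in both the segmentation
and the map mask. Viability regression is ordinary least squares of
viability on spheroid-mean μ̂ and/or β̂ via statsmodels; nested-model R²
monotonicity is asserted on random tables.

## Defaults

| parameter | default | rationale |
|---|---|---|
| 1/e² radii (Δx, Δy, Δz) | (20.0, 20.0, 6.1) μm | instrument-scale window: ~2× lateral resolution, ~2× axial resolution |
| n_freqs | 7 | odd, ≥3; more samples condition the slope without widening the band |
| freq span F | 1/(2πσ_z) | keeps \|G(f)\| ≥ e^(−1/2)·\|G(0)\| |
| kernel truncation | 4σ | <1e−4 of kernel mass dropped |
| mask margin | 3σ | boundary-affected shell |
| μ_r | 1.0 mm⁻¹ | 1% intralipid at 850 nm |
| compensation halfwidth | 1.0·μ_r | covers the physiological Δμ range symmetrically |
| apodization window | Hann | conventional; configurable |
| zero-pad factor | 4 | refines depth sampling 2× beyond the transform's native pitch |
| LF/FD window | 2√π σ_z | equal effective support for fair comparison |

## Known limitations

* β̂ is relative to the reference medium's backscatter (β_r is not
  measurable with a spectrophotometer); no absolute calibration is
  attempted.
* Gradual axial β changes alias into μ̂ (and vice versa at interfaces);
  grazing-incidence surfaces bias β̂ low by ~10%.
* Desk-scale AC accuracy is noise-floor-limited (~1% volume-level at
  128×128×512 under fully developed speckle); conclusions about the
  estimator's bias come from the noiseless closed-form tests.
* The confocal model must match between sample and reference; a
  mismatch is not detected and folds into μ̂.
* k-linearization, dispersion compensation and spectrometer calibration
  are upstream of this package and assumed done.
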