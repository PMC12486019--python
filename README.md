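# octoprops

Dual-parameter optical-property tomography for optical coherence
tomography (OCT) volumes: voxel-wise, depth-resolved maps of the
**normalized attenuation coefficient** (AC, μ̂) and the **normalized
backscattering coefficient** (BSC, β̂), estimated jointly with a complex
3D Gabor filter bank.

## Who this is for

Label-free monitoring of 3D cell cultures — tumour spheroids in
particular — needs quantitative readouts that do not require staining,
washing, or disruption. The intensity of an OCT A-line through a turbid
sample decays with the attenuation coefficient and scales with the
backscattering coefficient of the tissue; both change when cells undergo
drug- or immune-cell-induced apoptosis. This package implements the full
computational chain to turn raw OCT intensity volumes into paired AC/BSC
maps and per-spheroid metrics, plus a digital-phantom simulator so every
stage can be validated without an instrument.

## The method

OCT intensity in a homogeneous slab follows a Lambert–Beer law,

    I(x, y, z) = α · β(x, y, z) · exp(−2 ∫₀ᶻ μ(x, y, z′) dz′) · h(z),

with β the backscattering coefficient, μ the attenuation coefficient
(mm⁻¹), h(z) the confocal collection profile, and α a system constant.
Dividing each A-line by a reference acquisition of a homogeneous medium
with known attenuation μ_r (a 1% intralipid bath, μ_r ≈ 1.0 mm⁻¹ at
850 nm) cancels α and h(z):

    r(x, y, z) = (β/β_r) · exp(−2 ∫₀ᶻ (μ − μ_r) dz′).

The ratio volume is then filtered with a bank of complex 3D Gabor
filters — a shared Gaussian envelope with 1/e² radii (Δx, Δy, Δz),
modulated by axial spatial frequencies f — giving a local axial spectrum
G(f) at every voxel. For a locally exponential ratio ~exp(−a z):

* **arg G(f) = 2π σ_z² a f** — the phase is linear in f, and a weighted
  least-squares slope recovers a = 2(μ_s − μ_r), hence
  **μ̂ = μ_s/μ_r**;
* **|G(0)|** is the local mean ratio — after compensating the
  accumulated residual attenuation it gives **β̂ = β_s/β_r**.

Because the envelope is small (defaults Δx = Δy = 20 μm, Δz = 6.1 μm),
both estimates are depth-resolved rather than per-A-line, and the
lateral extent of the window averages speckle, which is what gives this
estimator its precision advantage over conventional per-A-line
log-fitting (LF) and Fourier-domain (FD) readouts — both of which are
included as baselines.

## Modules

| module                 | contents |
|------------------------|----------|
| `octoprops.io`         | TIFF / HDF5 / raw+JSON volume I/O, A-line reconstruction from interference spectra |
| `octoprops.phantom`    | declarative digital phantoms, Lambert–Beer forward model, speckle and noise-floor models |
| `octoprops.gabor`      | reference normalization, Gabor bank, AC/BSC estimators |
| `octoprops.baselines`  | LF and FD estimators, validation harness (`run_validation_suite`) |
| `octoprops.validation` | canned phantom-accuracy and backscatter-ladder studies |
| `octoprops.spheroid`   | segmentation, 3D morphometrics, radial profiles, viability regression |
| `octoprops.cli`        | `octoprops convert / recon / simulate / estimate / validate / quantify / regress` |

## Worked example

```python
import octoprops as op

# digital phantom: spheroid-like optical properties in an intralipid bath
phantom = op.make_homogeneous_phantom(
    mu=0.6, beta=0.12, shape=(96, 96, 384), spacing=(1.0, 1.0, 0.61), seed=7
)
sample = op.simulate_volume(phantom)
reference = op.simulate_reference(1.0, shape=phantom.shape,
                                  spacing=phantom.spacing, seed=1007)

bank = op.build_gabor_bank((20.0, 20.0, 6.1), spacing=phantom.spacing)
maps = op.estimate_acbsc(sample, reference, bank, mu_ref=1.0)

print(f"normalized AC  (true 0.60): {maps.ac[maps.mask].mean():.3f}")
print(f"normalized BSC (true 0.12): {maps.bsc[maps.mask].mean():.4f}")
print(f"valid voxels: {maps.mask.sum()} of {maps.mask.size}")
```

prints

```
normalized AC  (true 0.60): 0.607
normalized BSC (true 0.12): 0.1201
valid voxels: 458784 of 3538944
```

The phantom was built with μ_s = 0.6 mm⁻¹ against a μ_r = 1.0 mm⁻¹
reference and β = 0.12 relative backscatter, under fully developed
speckle; the estimator recovers both to ~1% at the volume level. The
mask excludes a 3σ filter margin and any voxels at the noise floor.

For spheroid work, `segment_spheroid` → `morphometry` gives volume,
height, Feret diameter, Wadell sphericity and projected circularity;
`radial_profile` bins the AC/BSC maps into concentric shells; and
`fit_viability_model` regresses assay viability on spheroid-mean μ̂ and
β̂ (single- or dual-parameter, nested R²).

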