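"""Digital OCT phantoms: the Lambert-Beer forward model with speckle.

The simulator is the test substrate for every estimator in this package.
A phantom is a declarative object: voxel maps of the scattering attenuation
coefficient ``mu`` (mm^-1) and the relative backscattering coefficient
``beta`` (dimensionless, in units of the reference medium's backscatter),
plus a confocal collection profile, a speckle model, a noise floor, and a
seed.  The speckle-free mean intensity at voxel ``(x, y, z)`` is

    I(x, y, z) = beta(x, y, z) * exp(-2 * integral_0^z mu dz') * h(z)

with the overall system constant fixed to 1 (the estimators only ever use
ratios of volumes, so absolute radiometry is deliberately not modelled).
The depth integral is a cumulative sum over voxel centres with a half-voxel
offset, which makes the noiseless log-intensity slope exactly ``-2 mu`` on
homogeneous blocks.

Fully developed speckle is modelled as i.i.d. unit-mean exponential
intensity multipliers -- the standard statistics of coherent imaging of
many sub-resolution scatterers.  A correlated-speckle variant draws a
complex circular-Gaussian field, smooths it to the requested correlation
radii, and takes the squared magnitude, rescaled to preserve the local
mean intensity.  The noise floor is additive unit-mean exponential
intensity scaled by the floor level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume import OCTVolume

__all__ = [
    "ConfocalModel",
    "SpeckleModel",
    "PhantomSpec",
    "make_homogeneous_phantom",
    "make_spheroid_phantom",
    "simulate_volume",
    "simulate_reference",
]


@dataclass
class ConfocalModel:
    """Depth-dependent collection efficiency h(z) of the focused beam.

    ``gaussian_focus`` uses the axial profile of a focused Gaussian beam,
    ``h(z) = 1 / (1 + ((z - focus_depth) / rayleigh_range)^2)``, with depth
    in micrometres.  ``none`` means h(z) = 1.
    """

    kind: str = "none"
    focus_depth: float = 0.0
    rayleigh_range: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian_focus"):
            raise ValueError(f"unknown confocal kind {self.kind!r}")
        if self.kind == "gaussian_focus" and self.rayleigh_range <= 0:
            raise ValueError("rayleigh_range must be > 0 for gaussian_focus")

    def profile(self, z_um: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.ones_like(z_um)
        u = (z_um - self.focus_depth) / self.rayleigh_range
        return 1.0 / (1.0 + u**2)


@dataclass
class SpeckleModel:
    """Multiplicative intensity noise model.

    ``exponential``: i.i.d. unit-mean exponential multipliers per voxel
    (fully developed speckle).  ``correlated_field``: speckle with a finite
    grain size set by ``correlation_radii`` (Gaussian 1/e^2-style radii in
    micrometres).  ``none``: no speckle.
    """

    kind: str = "exponential"
    correlation_radii: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "exponential", "correlated_field"):
            raise ValueError(f"unknown speckle kind {self.kind!r}")
        if self.kind == "correlated_field":
            if self.correlation_radii is None or any(
                r <= 0 for r in self.correlation_radii
            ):
                raise ValueError("correlated_field needs positive correlation_radii")


@dataclass
class PhantomSpec:
    """Declarative description of a digital phantom.

    ``mu_map`` is in mm^-1; ``beta_map`` is dimensionless (units of the
    reference medium's backscatter).  Both must match ``shape``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    mu_map: np.ndarray
    beta_map: np.ndarray
    confocal: ConfocalModel = field(default_factory=ConfocalModel)
    speckle: SpeckleModel = field(default_factory=SpeckleModel)
    noise_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)  # type: ignore[assignment]
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.mu_map = np.asarray(self.mu_map, dtype=np.float64)
        self.beta_map = np.asarray(self.beta_map, dtype=np.float64)
        if self.mu_map.shape != self.shape or self.beta_map.shape != self.shape:
            raise ValueError("mu_map and beta_map must match shape")
        if np.any(self.mu_map < 0) or np.any(self.beta_map < 0):
            raise ValueError("mu_map and beta_map must be non-negative")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")


def make_homogeneous_phantom(
    mu: float,
    beta: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    confocal: Optional[ConfocalModel] = None,
    speckle: Optional[SpeckleModel] = None,
    noise_floor: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """A uniform slab: constant ``mu`` (mm^-1) and ``beta`` everywhere."""
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        mu_map=np.full(shape, float(mu)),
        beta_map=np.full(shape, float(beta)),
        confocal=confocal or ConfocalModel(),
        speckle=speckle or SpeckleModel(),
        noise_floor=noise_floor,
        seed=seed,
    )


def make_spheroid_phantom(
    radius: float,
    center: tuple[float, float, float],
    mu_core: float,
    mu_shell: float,
    beta_core: float,
    beta_shell: float,
    shell_thickness: float,
    background_mu: float,
    background_beta: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    confocal: Optional[ConfocalModel] = None,
    speckle: Optional[SpeckleModel] = None,
    noise_floor: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """A spherical core/shell inclusion in a uniform background.

    Emulates a tumour spheroid whose optical changes start at the periphery:
    voxels within ``shell_thickness`` (micrometres) of the surface take the
    shell values, deeper voxels the core values, everything outside the
    sphere the background values.  ``radius`` and ``center`` are in
    micrometres on the physical grid (voxel centres at ``(i + 1/2) * d``).
    """
    if not (radius > shell_thickness >= 0):
        raise ValueError("need radius > shell_thickness >= 0")
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing)
    extents = [n * s for n, s in zip(shape, spacing)]
    for c, ext, name in zip(center, extents, "xyz"):
        if c - radius < 0 or c + radius > ext:
            raise ValueError(
                f"sphere (centre {c} um, radius {radius} um) exceeds grid along {name} "
                f"(extent {ext} um)"
            )
    coords = [
        (np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)
    ]
    dist = np.sqrt(
        (coords[0][:, None, None] - center[0]) ** 2
        + (coords[1][None, :, None] - center[1]) ** 2
        + (coords[2][None, None, :] - center[2]) ** 2
    )
    inside = dist <= radius
    core = dist <= radius - shell_thickness
    shell = inside & ~core
    mu_map = np.full(shape, float(background_mu))
    beta_map = np.full(shape, float(background_beta))
    mu_map[shell], beta_map[shell] = mu_shell, beta_shell
    mu_map[core], beta_map[core] = mu_core, beta_core
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        mu_map=mu_map,
        beta_map=beta_map,
        confocal=confocal or ConfocalModel(),
        speckle=speckle or SpeckleModel(),
        noise_floor=noise_floor,
        seed=seed,
    )


def mean_intensity(phantom: PhantomSpec) -> np.ndarray:
    """The speckle-free mean intensity of the forward model."""
    dz_mm = phantom.spacing[2] * 1e-3
    # cumulative attenuation at voxel centres: half-voxel offset so the
    # noiseless log slope is exactly -2*mu on homogeneous blocks
    att = (np.cumsum(phantom.mu_map, axis=2) - phantom.mu_map / 2.0) * dz_mm
    z_um = (np.arange(phantom.shape[2]) + 0.5) * phantom.spacing[2]
    h = phantom.confocal.profile(z_um)[None, None, :]
    return phantom.beta_map * np.exp(-2.0 * att) * h


def _correlated_speckle(
    mean: np.ndarray,
    radii_um: tuple[float, float, float],
    spacing: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlated fully developed speckle with local mean preserved.

    A complex circular-Gaussian field with local variance equal to the mean
    intensity is smoothed by a Gaussian of the correlation radii; the
    squared magnitude is then rescaled so its expectation equals the input
    mean (the expectation of the smoothed power is the same Gaussian^2
    smoothing applied to the mean).
    """
    sig_vox = [max(r / 2.0 / s, 1e-6) for r, s in zip(radii_um, spacing)]
    shape = mean.shape
    g = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)
    field = g * np.sqrt(mean)
    # periodic smoothing keeps the field statistics uniform, so the
    # unit-mean rescaling below is exact everywhere
    sm = _kernel_smooth(field.real, sig_vox) + 1j * _kernel_smooth(field.imag, sig_vox)
    power = np.abs(sm) ** 2
    # E[power] = sum_k w_k^2 * mean_k  (correlation of the squared kernel)
    expected = _kernel_smooth(mean, sig_vox, squared=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(expected > 0, power * (mean / expected), 0.0)
    return out


def _kernel_smooth(arr: np.ndarray, sig_vox: list[float], squared: bool = False) -> np.ndarray:
    out = arr
    for axis, s in enumerate(sig_vox):
        radius = max(int(np.ceil(4.0 * s)), 1)
        x = np.arange(-radius, radius + 1, dtype=np.float64)
        k = np.exp(-(x**2) / (2.0 * s**2))
        k /= k.sum()
        out = ndimage.correlate1d(out, k**2 if squared else k, axis=axis, mode="wrap")
    return out


def simulate_volume(phantom: PhantomSpec) -> OCTVolume:
    """Draw one seeded OCT volume from a phantom.

    Identical :class:`PhantomSpec` instances give bit-identical output.
    """
    rng = np.random.default_rng(phantom.seed)
    mean = mean_intensity(phantom)
    if phantom.speckle.kind == "none":
        data = mean.copy()
    elif phantom.speckle.kind == "exponential":
        data = mean * rng.exponential(1.0, size=mean.shape)
    else:
        data = _correlated_speckle(
            mean, phantom.speckle.correlation_radii, phantom.spacing, rng
        )
    if phantom.noise_floor > 0:
        data = data + phantom.noise_floor * rng.exponential(1.0, size=mean.shape)
    return OCTVolume(
        data=data,
        spacing=phantom.spacing,
        meta={"source": "octoprops.phantom", "seed": phantom.seed},
    )


def simulate_reference(
    mu_r: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    beta_r: float = 1.0,
    confocal: Optional[ConfocalModel] = None,
    speckle: Optional[SpeckleModel] = None,
    noise_floor: float = 0.0,
    seed: int = 1,
) -> OCTVolume:
    """Simulate a homogeneous reference acquisition (intralipid analogue).

    The reference must share the confocal model of the sample volume it
    will normalize so that the collection profile cancels in the ratio.
    """
    if mu_r < 0:
        raise ValueError("mu_r must be non-negative")
    phantom = make_homogeneous_phantom(
        mu=mu_r,
        beta=beta_r,
        shape=shape,
        spacing=spacing,
        confocal=confocal,
        speckle=speckle,
        noise_floor=noise_floor,
        seed=seed,
    )
    return simulate_volume(phantom)
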