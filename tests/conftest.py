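"""Shared fixtures: small helpers and three moderately expensive
end-to-end estimations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import octoprops as op

# paper-scale filter: 1/e^2 radii in um
RADII = (20.0, 20.0, 6.1)
MU_REF = 1.0  # mm^-1, intralipid-like reference

# core/shell optical endpoints reported for treated tumour spheroids:
# normalized AC 0.40 (core) / 0.82 (shell), BSC 0.09 / 0.20
CORE_AC, SHELL_AC = 0.40, 0.82
CORE_BSC, SHELL_BSC = 0.09, 0.20


def exponential_ratio(
    rate_mm: float,
    level: float = 1.0,
    shape=(32, 32, 160),
    spacing=(2.0, 2.0, 1.0),
    mu_ref: float = MU_REF,
) -> op.RatioVolume:
    """A noiseless reference-normalized volume decaying as exp(-rate * z)."""
    nz = shape[2]
    z_mm = (np.arange(nz) + 0.5) * spacing[2] * 1e-3
    data = np.broadcast_to(
        level * np.exp(-rate_mm * z_mm)[None, None, :], shape
    ).copy()
    return op.RatioVolume(
        data=data,
        spacing=spacing,
        mu_ref=mu_ref,
        floor_mask=np.zeros(shape, dtype=bool),
    )


@pytest.fixture(scope="session")
def small_bank():
    return op.build_gabor_bank(RADII, spacing=(2.0, 2.0, 1.0))


def _spheroid_case(speckle_kind: str, seed: int):
    """Core/shell spheroid in a medium-like background, estimated with a
    12 um lateral window (the 35 um shell spans ~6 lateral sigma, so the
    window resolves it)."""
    spacing = (1.5, 1.5, 0.8)
    shape = (160, 160, 280)
    center = (120.0, 120.0, 112.0)
    radius = 90.0
    phantom = op.make_spheroid_phantom(
        radius=radius,
        center=center,
        mu_core=CORE_AC,
        mu_shell=SHELL_AC,
        beta_core=CORE_BSC,
        beta_shell=SHELL_BSC,
        shell_thickness=35.0,
        background_mu=0.30,
        background_beta=0.07,
        shape=shape,
        spacing=spacing,
        seed=seed,
        speckle=op.SpeckleModel(kind=speckle_kind),
    )
    sample = op.simulate_volume(phantom)
    reference = op.simulate_reference(
        MU_REF,
        shape=shape,
        spacing=spacing,
        seed=1000 + seed,
        speckle=op.SpeckleModel(kind=speckle_kind),
    )
    bank = op.build_gabor_bank((12.0, 12.0, 6.1), spacing=spacing)
    amap = op.estimate_acbsc(sample, reference, bank, mu_ref=MU_REF)
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    r = np.sqrt(
        (coords[0][:, None, None] - center[0]) ** 2
        + (coords[1][None, :, None] - center[1]) ** 2
        + (coords[2][None, None, :] - center[2]) ** 2
    )
    return {
        "phantom": phantom,
        "map": amap,
        "bank": bank,
        "radius": radius,
        "r": r,
        "spacing": spacing,
    }


@pytest.fixture(scope="session")
def spheroid_noiseless():
    return _spheroid_case("none", seed=0)


@pytest.fixture(scope="session")
def spheroid_speckled():
    return _spheroid_case("exponential", seed=11)


@pytest.fixture(scope="session")
def layered_speckled():
    """Flat core/shell layers under fully developed speckle, estimated
    with the paper-scale bank; the geometry a spheroid presents near its
    pole, with enough voxels for tight region statistics."""
    spacing = (1.0, 1.0, 0.61)
    shape = (160, 160, 512)
    z = (np.arange(shape[2]) + 0.5) * spacing[2]
    mu = np.full(shape, 0.15)
    beta = np.full(shape, 0.02)
    shell = (z >= 40) & (z < 100)
    core = (z >= 100) & (z < 280)
    mu[:, :, shell], beta[:, :, shell] = SHELL_AC, SHELL_BSC
    mu[:, :, core], beta[:, :, core] = CORE_AC, CORE_BSC
    phantom = op.PhantomSpec(
        shape=shape, spacing=spacing, mu_map=mu, beta_map=beta, seed=3
    )
    sample = op.simulate_volume(phantom)
    reference = op.simulate_reference(MU_REF, shape=shape, spacing=spacing, seed=903)
    bank = op.build_gabor_bank(RADII, spacing=spacing)
    amap = op.estimate_acbsc(sample, reference, bank, mu_ref=MU_REF)
    shell_probe = amap.mask & ((z >= 55) & (z < 85))[None, None, :]
    core_probe = amap.mask & ((z >= 120) & (z < 260))[None, None, :]
    return {"map": amap, "shell_probe": shell_probe, "core_probe": core_probe}
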