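"""Canned validation protocols: the digital-phantom accuracy study and
the backscatter concentration ladder.

These are the package's reference experiments.  The phantom family
reproduces the numerical validation of the Gabor estimator: homogeneous
slabs with normalized AC / BSC levels spanning the range reported for
tumour spheroids, fully developed speckle, a matched simulated reference,
and the paper-scale filter radii.  The ladder is the in-silico analogue
of an intralipid concentration series: attenuation and backscatter both
scale with concentration, and the volume-level backscatter estimate is
scored for linearity and repeatability.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .baselines import PrecisionReport, run_validation_suite
from .gabor import build_gabor_bank
from .phantom import make_homogeneous_phantom

__all__ = [
    "default_phantom_family",
    "phantom_accuracy_study",
    "bsc_ladder_study",
    "LADDER_CONCENTRATIONS",
]

#: normalized (AC, BSC) levels of the phantom family; the endpoints match
#: the values reported for untreated vs fully treated spheroids
FAMILY_LEVELS = ((0.4, 0.09), (0.6, 0.12), (0.8, 0.20), (0.5, 0.15))

#: concentration multipliers of the in-silico intralipid ladder
LADDER_CONCENTRATIONS = (0.5, 1.0, 2.5, 5.0)

MU_REF = 1.0  # mm^-1 at 850 nm, 1% intralipid reference
RADII = (20.0, 20.0, 6.1)  # um, 1/e^2 filter radii
SPACING = (1.0, 1.0, 0.61)  # um, voxel pitch of the simulated volumes


def default_phantom_family(shape=(128, 128, 512)):
    """Homogeneous speckled phantoms at the family's (AC, BSC) levels."""
    return [
        make_homogeneous_phantom(mu * MU_REF, beta, shape, SPACING)
        for mu, beta in FAMILY_LEVELS
    ]


def phantom_accuracy_study(
    seeds: Sequence[int],
    shape=(128, 128, 512),
) -> dict:
    """Accuracy of the Gabor AC/BSC estimates on the phantom family.

    Per phantom and seed, a sample volume and matched reference are
    simulated; the phantom-level estimate is the mean of the voxel map
    over the valid interior, and the absolute relative error against
    ground truth is averaged over all phantoms and seeds.

    Returns a dict with ``ac_error_pct``, ``bsc_error_pct``,
    ``n_realizations`` and the per-phantom reports.
    """
    bank = build_gabor_bank(RADII, spacing=SPACING)
    reports = run_validation_suite(
        default_phantom_family(shape),
        bank,
        mu_ref=MU_REF,
        methods=("gabor",),
        seeds=list(seeds),
    )
    return {
        "ac_error_pct": float(np.mean([r.mean_rel_error_ac for r in reports])),
        "bsc_error_pct": float(np.mean([r.mean_rel_error_bsc for r in reports])),
        "n_realizations": sum(r.n_realizations for r in reports),
        "reports": reports,
    }


def bsc_ladder_study(
    seeds: Sequence[int],
    shape=(64, 64, 256),
) -> dict:
    """Backscatter ladder: volume-level repeatability and linearity.

    Simulates homogeneous media at 0.5x .. 5x the reference concentration
    (attenuation and backscatter both scale), estimates the normalized
    backscatter of each, and reports the per-concentration coefficient of
    variation plus the R^2 of mean estimated vs true backscatter.
    """
    bank = build_gabor_bank(RADII, spacing=SPACING)
    phantoms = [
        make_homogeneous_phantom(c * MU_REF, c, shape, SPACING)
        for c in LADDER_CONCENTRATIONS
    ]
    reports: list[PrecisionReport] = run_validation_suite(
        phantoms, bank, mu_ref=MU_REF, methods=("gabor",), seeds=list(seeds)
    )
    means = np.array([np.mean(r.estimates_bsc) for r in reports])
    truth = np.array(LADDER_CONCENTRATIONS, dtype=float)
    fit = np.polyfit(truth, means, 1)
    resid = means - np.polyval(fit, truth)
    r2 = 1.0 - float(np.sum(resid**2) / np.sum((means - means.mean()) ** 2))
    return {
        "cv_pct": [float(r.cv_bsc) for r in reports],
        "mean_bsc": means.tolist(),
        "true_bsc": truth.tolist(),
        "r_squared": r2,
        "reports": reports,
    }
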