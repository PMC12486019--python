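"""The in-memory OCT volume container.

Every module in this package exchanges 3D intensity data through
:class:`OCTVolume`: a non-negative real array in fixed ``(x, y, z)`` axis
order, where ``z`` is optical depth increasing into the sample, together
with the physical voxel spacing in micrometres.  On-disk layouts are
permuted to this convention at load time so that all downstream depth
integrals run along the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["OCTVolume"]

#: canonical in-memory axis order
CANONICAL_AXES = "xyz"


@dataclass
class OCTVolume:
    """A 3D OCT intensity volume with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of non-negative, finite intensities (arbitrary units),
        axis order ``(x, y, z)`` with ``z`` the depth axis, index 0 at the
        shallowest sample.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in micrometres; all entries > 0.
    meta
        Free-form provenance (source path, wavelength in nm, comments...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        n_bad = int(np.count_nonzero(~np.isfinite(self.data)))
        if n_bad:
            raise ValueError(f"data contains {n_bad} non-finite voxels")
        n_neg = int(np.count_nonzero(self.data < 0))
        if n_neg:
            raise ValueError(f"data contains {n_neg} negative voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        """Voxel spacing in millimetres (attenuation is reported in mm^-1)."""
        return tuple(s * 1e-3 for s in self.spacing)  # type: ignore[return-value]

    def depth_axis_mm(self) -> np.ndarray:
        """Physical depth of voxel centres along z, in millimetres.

        Voxel ``k`` is centred at ``(k + 1/2) * dz``; the half-voxel offset
        keeps discrete log-intensity slopes exactly ``-2 mu`` on
        homogeneous media (see the forward model in :mod:`octoprops.phantom`).
        """
        dz_mm = self.spacing[2] * 1e-3
        return (np.arange(self.shape[2]) + 0.5) * dz_mm

    def same_grid(self, other: "OCTVolume", rtol: float = 1e-9) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=rtol
        )


def permute_to_canonical(data: np.ndarray, axes: str) -> np.ndarray:
    """Permute an on-disk array with axis labels ``axes`` to ``(x, y, z)``.

    ``axes`` is a 3-character permutation of ``"xyz"`` giving the meaning of
    each on-disk dimension, e.g. ``"zyx"`` for page-stacked TIFF.
    """
    axes = axes.lower()
    if sorted(axes) != ["x", "y", "z"]:
        raise ValueError(f"axes must be a permutation of 'xyz', got {axes!r}")
    if data.ndim != 3:
        raise ValueError("expected a 3D array")
    order = [axes.index(a) for a in CANONICAL_AXES]
    return np.transpose(data, order)


def permute_from_canonical(data: np.ndarray, axes: str) -> np.ndarray:
    """Inverse of :func:`permute_to_canonical`."""
    axes = axes.lower()
    if sorted(axes) != ["x", "y", "z"]:
        raise ValueError(f"axes must be a permutation of 'xyz', got {axes!r}")
    order = [CANONICAL_AXES.index(a) for a in axes]
    return np.transpose(data, order)
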