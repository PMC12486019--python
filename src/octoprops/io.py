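"""Reading and writing OCT volumes, and A-line reconstruction from spectra.

Supported on-disk formats:

* multi-page TIFF (float32, pages stacked along z, each page ``(y, x)``)
  with a JSON sidecar ``<file>.json`` carrying voxel spacing;
* HDF5 with a single ``data`` dataset and ``spacing_um`` / ``axes`` attrs;
* raw binary with a JSON sidecar giving ``shape``, ``dtype``, ``spacing_um``
  and ``axes``.

Spacing is never defaulted: a file without spacing metadata is an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import tifffile
from scipy.signal import get_window

from .volume import OCTVolume, permute_from_canonical, permute_to_canonical

__all__ = ["read_volume", "write_volume", "SpectralFrame", "reconstruct_alines"]

#: on-disk axis order used when this package writes TIFF stacks
_TIFF_AXES = "zyx"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _detect_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint:
        return format_hint.lower()
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if suffix in (".raw", ".bin", ".dat"):
        return "raw"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format_hint")


def _validate_payload(data: np.ndarray, sanitize: bool, source: str) -> np.ndarray:
    data = np.asarray(data, dtype=np.float64)
    bad = ~np.isfinite(data)
    neg = np.isfinite(data) & (data < 0)
    n_bad, n_neg = int(bad.sum()), int(neg.sum())
    if n_bad or n_neg:
        if not sanitize:
            raise ValueError(
                f"{source}: {n_bad} non-finite and {n_neg} negative voxels; "
                "pass sanitize=True to clip to 0"
            )
        data = data.copy()
        data[bad | neg] = 0.0
    return data


def read_volume(
    path: str | Path,
    format_hint: Optional[str] = None,
    sanitize: bool = False,
) -> OCTVolume:
    """Load an OCT volume, normalizing the axis order to ``(x, y, z)``.

    Parameters
    ----------
    path
        TIFF stack, HDF5 file, or raw binary (with JSON sidecar).
    format_hint
        ``"tiff"``, ``"hdf5"`` or ``"raw"``; inferred from the suffix when
        omitted.
    sanitize
        Clip negative and non-finite voxels to 0 instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _detect_format(path, format_hint)

    if fmt == "tiff":
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            raw = raw[None]
        side = _sidecar_path(path)
        if not side.exists():
            raise ValueError(f"TIFF volume {path} has no spacing sidecar {side}")
        meta = json.loads(side.read_text())
        axes = meta.get("axes", _TIFF_AXES)
        spacing = meta.get("spacing_um")
    elif fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise ValueError(f"{path}: no 'data' dataset")
            dset = f["data"]
            raw = dset[()]
            spacing = dset.attrs.get("spacing_um", f.attrs.get("spacing_um"))
            axes = str(dset.attrs.get("axes", f.attrs.get("axes", "xyz")))
            meta = {k: v for k, v in dset.attrs.items() if k not in ("spacing_um", "axes")}
    else:  # raw
        side = _sidecar_path(path)
        if not side.exists():
            raise ValueError(f"raw volume {path} has no JSON sidecar {side}")
        meta = json.loads(side.read_text())
        for key in ("shape", "dtype", "spacing_um"):
            if key not in meta:
                raise ValueError(f"sidecar {side} missing required key {key!r}")
        shape = tuple(int(n) for n in meta["shape"])
        raw = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        if raw.size != int(np.prod(shape)):
            raise ValueError(
                f"{path}: {raw.size} samples on disk, sidecar shape {shape} "
                f"needs {int(np.prod(shape))}"
            )
        raw = raw.reshape(shape)
        axes = meta.get("axes", "xyz")
        spacing = meta["spacing_um"]

    if spacing is None:
        raise ValueError(f"{path}: no voxel spacing in metadata; refusing to default")
    spacing = tuple(float(s) for s in np.asarray(spacing).ravel())
    if len(spacing) != 3:
        raise ValueError(f"{path}: spacing must have three entries, got {spacing}")

    data = permute_to_canonical(np.asarray(raw), axes)
    data = _validate_payload(data, sanitize, str(path))
    info = {"source": str(path), "format": fmt}
    if isinstance(meta, dict):
        info.update({k: v for k, v in meta.items() if k not in ("shape", "dtype", "spacing_um", "axes")})
    return OCTVolume(data=data, spacing=spacing, meta=info)


def write_volume(volume: OCTVolume, path: str | Path, format_hint: Optional[str] = None) -> None:
    """Write a volume so that :func:`read_volume` round-trips it.

    TIFF output is float32 (values preserved to 32-bit precision); HDF5 and
    raw binary keep float64 and round-trip bit-exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    fmt = _detect_format(path, format_hint)

    if fmt == "tiff":
        pages = permute_from_canonical(volume.data.astype(np.float32), _TIFF_AXES)
        tifffile.imwrite(path, pages, photometric="minisblack")
        _sidecar_path(path).write_text(
            json.dumps({"spacing_um": list(volume.spacing), "axes": _TIFF_AXES})
        )
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=volume.data)
            dset.attrs["spacing_um"] = np.asarray(volume.spacing, dtype=np.float64)
            dset.attrs["axes"] = "xyz"
    else:
        volume.data.astype(np.float64).tofile(path)
        _sidecar_path(path).write_text(
            json.dumps(
                {
                    "shape": list(volume.shape),
                    "dtype": "float64",
                    "spacing_um": list(volume.spacing),
                    "axes": "xyz",
                }
            )
        )


@dataclass
class SpectralFrame:
    """A frame of raw interference spectra (A-lines x spectral samples).

    ``background`` defaults to the mean spectrum across A-lines when absent.
    ``zero_pad_factor`` multiplies the spectral length before the DFT,
    refining the depth sampling of the reconstructed A-lines.
    """

    spectra: np.ndarray
    background: Optional[np.ndarray] = None
    window_name: str = "hann"
    zero_pad_factor: int = 4

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be 2D (A-lines x spectral samples)")
        if self.spectra.shape[1] < 2:
            raise ValueError("need at least 2 spectral samples")
        if int(self.zero_pad_factor) < 1:
            raise ValueError("zero_pad_factor must be >= 1")
        self.zero_pad_factor = int(self.zero_pad_factor)
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=np.float64)
            if self.background.shape != (self.spectra.shape[1],):
                raise ValueError("background must match the spectral sample count")


def reconstruct_alines(frame: SpectralFrame) -> np.ndarray:
    """Reconstruct A-line intensity profiles from interference spectra.

    Per A-line: subtract the background spectrum, apodize, zero-pad to
    ``zero_pad_factor`` times the original length, Fourier transform, and
    keep the squared magnitude of the positive-depth half (the first half
    of the padded transform).

    Returns
    -------
    ndarray
        ``(n_alines, zero_pad_factor * n_samples // 2)`` non-negative array.
    """
    spectra = frame.spectra
    n_alines, n_samples = spectra.shape
    background = (
        frame.background if frame.background is not None else spectra.mean(axis=0)
    )
    fringes = spectra - background[None, :]
    if not np.any(fringes):
        warnings.warn("all-zero spectra after background subtraction", stacklevel=2)
    window = get_window(frame.window_name, n_samples, fftbins=True)
    padded_len = frame.zero_pad_factor * n_samples
    spectrum = np.fft.fft(fringes * window[None, :], n=padded_len, axis=1)
    half = spectrum[:, : padded_len // 2]
    return np.abs(half) ** 2
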