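"""Image, PSF, trace and config file handling.

Grayscale PNG/TIFF images (8- or 16-bit) are read into [0, 1] float arrays;
DICOM files are read via pydicom (pixel data with rescale slope/intercept
applied, then min-max mapped to [0, 1]). Written images are clipped to
[0, 1] and scaled to the full integer range. PSFs, traces, metrics and
manifests use plain-text formats so runs stay inspectable and diffable.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np

from ._validation import as_image
from .degradation import PSF
from .exceptions import InvalidParameterError
from .solver import SolveTrace, SolverConfig

_DICOM_EXTS = (".dcm", ".dicom")


def read_image(path: str) -> np.ndarray:
    """Read a grayscale image as a [0, 1] float64 array."""
    ext = os.path.splitext(path)[1].lower()
    if ext in _DICOM_EXTS:
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        return as_image(arr, name=path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise InvalidParameterError(
            f"{path}: color images are not supported (got shape {arr.shape})"
        )
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    else:
        arr = arr.astype(np.float64)
    return as_image(arr, name=path)


def write_image(path: str, img, bit_depth: int = 16) -> None:
    """Write a float image, clipped to [0, 1] and scaled to 8 or 16 bits."""
    img = as_image(img)
    if bit_depth == 8:
        out = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    elif bit_depth == 16:
        out = (np.clip(img, 0.0, 1.0) * 65535.0).round().astype(np.uint16)
    else:
        raise InvalidParameterError(f"bit_depth must be 8 or 16, got {bit_depth}")
    iio.imwrite(path, out)


def save_psf_text(path: str, psf: PSF | np.ndarray) -> None:
    """Export a PSF kernel as a whitespace-separated row-major text matrix."""
    kernel = psf.kernel if isinstance(psf, PSF) else np.asarray(psf)
    np.savetxt(path, kernel, fmt="%.17g")


def load_psf_text(path: str) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))


def write_trace_csv(path: str, trace: SolveTrace) -> None:
    """Iteration, objective and step-norm columns of a solve trace."""
    with open(path, "w") as fh:
        fh.write("iteration,objective,step_norm\n")
        for k, (obj, step) in enumerate(zip(trace.objective, trace.step_norm), start=1):
            fh.write(f"{k},{obj:.17g},{step:.17g}\n")


METRICS_HEADER = "image_id,noise_family,ssim,isnr,snr,wall_time_s"


def write_metrics_csv(path: str, rows: Iterable[str]) -> None:
    with open(path, "w") as fh:
        fh.write(METRICS_HEADER + "\n")
        for row in rows:
            fh.write(row + "\n")


_CONFIG_TYPES = {
    "step_size": float,
    "reg_weight": float,
    "regularizer": str,
    "max_iters": int,
    "rel_tol": float,
}


def read_solver_config(path: str, overrides: Mapping | None = None) -> SolverConfig:
    """Parse a ``key = value`` solver config file.

    Recognized keys: step_size, reg_weight, regularizer, max_iters, rel_tol.
    ``overrides`` (e.g. from CLI flags) take precedence; entries with value
    ``None`` are ignored.
    """
    values: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidParameterError(
                    f"{path}:{lineno}: expected 'key = value', got {raw.strip()!r}"
                )
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in _CONFIG_TYPES:
                raise InvalidParameterError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _CONFIG_TYPES[key](val)
    for key, val in (overrides or {}).items():
        if val is not None:
            if key not in _CONFIG_TYPES:
                raise InvalidParameterError(f"unknown config key {key!r}")
            values[key] = val
    return SolverConfig(**values)


def write_manifest(path: str, params: Mapping) -> None:
    """Record every parameter and seed of a run as ``key = value`` lines."""
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"{key} = {params[key]}\n")
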