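"""Input validation helpers shared across modules."""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidParameterError


def as_image(arr, *, name: str = "image") -> np.ndarray:
    """Coerce to a validated 2-D float64 intensity array.

    Accepts any array-like; requires 2-D shape with both dimensions >= 1 and
    all entries finite. Values are NOT clipped: solver iterates and degraded
    observations legitimately leave [0, 1].
    """
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim != 2:
        raise InvalidParameterError(
            f"{name} must be a 2-D array, got ndim={a.ndim}"
        )
    if a.shape[0] < 1 or a.shape[1] < 1:
        raise InvalidParameterError(f"{name} must be at least 1x1, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidParameterError(f"{name} contains non-finite values")
    return a


def check_same_shape(a: np.ndarray, b: np.ndarray, *, names=("first", "second")) -> None:
    if a.shape != b.shape:
        raise InvalidParameterError(
            f"{names[0]} shape {a.shape} != {names[1]} shape {b.shape}"
        )


def check_unit_interval(a: np.ndarray, *, name: str = "image", atol: float = 0.0) -> None:
    lo, hi = float(a.min()), float(a.max())
    if lo < -atol or hi > 1.0 + atol:
        raise InvalidParameterError(
            f"{name} must lie in [0, 1], got range [{lo:.6g}, {hi:.6g}]"
        )
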