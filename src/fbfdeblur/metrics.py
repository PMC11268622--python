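"""Restoration-quality metrics: SSIM, ISNR and SNR.

SSIM here is the *global-statistics* form: one luminance/contrast/structure
ratio computed from the means, population standard deviations and covariance
of the whole image pair. A sliding-window mean SSIM (the common default in
image-processing toolboxes) is available via ``windowed=True``, which
delegates to scikit-image. ISNR and SNR are the standard dB ratios of sums
of squared intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim

from ._validation import as_image, check_same_shape
from .exceptions import InvalidParameterError


@dataclass(frozen=True)
class SsimConstants:
    """Stabilizing constants of the SSIM ratio.

    Defaults are the conventional c1 = (0.01 R)^2, c2 = (0.03 R)^2 for
    dynamic range R (1.0 for [0, 1] images).
    """

    c1: float = 1e-4
    c2: float = 9e-4
    dynamic_range: float = 1.0

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0:
            raise InvalidParameterError("c1 and c2 must be > 0")
        if self.dynamic_range <= 0:
            raise InvalidParameterError("dynamic_range must be > 0")

    @classmethod
    def for_range(cls, dynamic_range: float) -> "SsimConstants":
        return cls(
            c1=(0.01 * dynamic_range) ** 2,
            c2=(0.03 * dynamic_range) ** 2,
            dynamic_range=dynamic_range,
        )


def ssim(x, y, constants: SsimConstants | None = None, windowed: bool = False) -> float:
    """Structural similarity between two images.

    Global statistics by default (population convention, divide by N);
    ``windowed=True`` computes the scikit-image sliding-window mean SSIM
    instead. Bounded above by 1, attained exactly when ``x == y``.
    """
    x = as_image(x, name="x")
    y = as_image(y, name="y")
    check_same_shape(x, y, names=("x", "y"))
    constants = constants or SsimConstants()
    if windowed:
        return float(
            _skimage_ssim(
                x,
                y,
                data_range=constants.dynamic_range,
                gaussian_weights=False,
            )
        )
    mx, my = float(x.mean()), float(y.mean())
    vx = float(np.mean((x - mx) ** 2))
    vy = float(np.mean((y - my) ** 2))
    cov = float(np.mean((x - mx) * (y - my)))
    c1, c2 = constants.c1, constants.c2
    return ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )


def isnr(clean, observed, estimate) -> float:
    """Improvement in signal-to-noise ratio, in dB.

    ``10 log10(||x - y||^2 / ||x - x_n||^2)`` with x clean, y observed and
    x_n the estimate. Positive when the estimate is closer to the clean
    image (in squared error) than the observation; +inf for a perfect
    estimate.
    """
    clean = as_image(clean, name="clean")
    observed = as_image(observed, name="observed")
    estimate = as_image(estimate, name="estimate")
    check_same_shape(clean, observed, names=("clean", "observed"))
    check_same_shape(clean, estimate, names=("clean", "estimate"))
    num = float(np.sum((clean - observed) ** 2))
    den = float(np.sum((clean - estimate) ** 2))
    if den == 0.0:
        return math.inf
    return 10.0 * math.log10(num / den) if num > 0 else -math.inf


def snr(clean, estimate) -> float:
    """Signal-to-noise ratio of an estimate, in dB:
    ``10 log10(||x||^2 / ||x - x_n||^2)``; +inf for a perfect estimate."""
    clean = as_image(clean, name="clean")
    estimate = as_image(estimate, name="estimate")
    check_same_shape(clean, estimate, names=("clean", "estimate"))
    sig = float(np.sum(clean**2))
    if sig == 0.0:
        raise InvalidParameterError("clean image is all-zero; SNR undefined")
    err = float(np.sum((clean - estimate) ** 2))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(sig / err)


@dataclass(frozen=True)
class MetricsReport:
    """The three quality numbers for one restoration."""

    ssim: float
    isnr: float
    snr: float

    def as_csv_row(
        self, image_id: str = "", noise_family: str = "", wall_time: float = float("nan")
    ) -> str:
        return (
            f"{image_id},{noise_family},{self.ssim:.6f},"
            f"{self.isnr:.6f},{self.snr:.6f},{wall_time:.3f}"
        )


def evaluate(clean, observed, estimate, constants: SsimConstants | None = None) -> MetricsReport:
    """Bundle SSIM(clean, estimate), ISNR and SNR into one report."""
    return MetricsReport(
        ssim=ssim(clean, estimate, constants),
        isnr=isnr(clean, observed, estimate),
        snr=snr(clean, estimate),
    )
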