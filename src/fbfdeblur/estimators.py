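"""Scikit-learn style estimators wrapping the degradation and restoration steps.

Both estimators operate on a single 2-D grayscale image (not the usual
samples-by-features matrix): degradation and deconvolution are per-image
transforms with hyperparameters, so ``get_params``/``set_params``/``clone``
and pipeline composition work as usual while ``fit``/``transform`` take the
image itself. A two-stage ``Pipeline([("degrade", MotionBlurDegrader()),
("restore", TsengDeconvolver())])`` reproduces the full simulation study.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import as_image
from .degradation import (
    DegradationSpec,
    DegradedObservation,
    PSF,
    degrade,
    make_motion_psf,
)
from .solver import RestorationProblem, SolverConfig, tseng_solve


class MotionBlurDegrader(TransformerMixin, BaseEstimator):
    """Simulate ``y = D x + eta``: motion blur plus Gaussian/Poisson noise.

    Parameters mirror :class:`~fbfdeblur.degradation.DegradationSpec`;
    defaults are the reference protocol (length-30 blur at 60 degrees,
    Gaussian variance 0.001).

    Attributes
    ----------
    psf_ : PSF
        The rasterized motion kernel, available after ``fit``.
    observation_ : DegradedObservation
        Full record of the last degradation performed by ``transform``.
    """

    def __init__(
        self,
        psf_length: float = 30.0,
        psf_angle: float = 60.0,
        noise_family: str = "gaussian",
        noise_level: float = 0.001,
        seed: int = 0,
        boundary: str = "circular",
    ):
        self.psf_length = psf_length
        self.psf_angle = psf_angle
        self.noise_family = noise_family
        self.noise_level = noise_level
        self.seed = seed
        self.boundary = boundary

    def _spec(self) -> DegradationSpec:
        return DegradationSpec(
            psf_length=self.psf_length,
            psf_angle=self.psf_angle,
            noise_family=self.noise_family,
            noise_level=self.noise_level,
            seed=self.seed,
            boundary=self.boundary,
        )

    def fit(self, X=None, y=None):
        """Validate parameters and rasterize the PSF."""
        spec = self._spec()  # validates
        self.psf_ = make_motion_psf(spec.psf_length, spec.psf_angle)
        return self

    def transform(self, X) -> np.ndarray:
        """Degrade a clean [0, 1] image; returns the observed image."""
        if not hasattr(self, "psf_"):
            self.fit()
        self.observation_ = degrade(as_image(X, name="clean"), self._spec())
        return self.observation_.observed


class TsengDeconvolver(TransformerMixin, BaseEstimator):
    """Restore a motion-blurred, noisy image by forward-backward-forward
    splitting applied to ``min_x 1/2 ||Dx - y||^2 + mu g(x)``.

    The blur is assumed known: either pass ``psf`` explicitly (a
    :class:`~fbfdeblur.degradation.PSF` or raw kernel) or give
    ``psf_length``/``psf_angle`` and the kernel is rasterized. ``step_size``
    (lam) and ``reg_weight`` (mu) default to the reference settings
    lam = 0.001, mu = 0.3.

    Attributes
    ----------
    image_ : ndarray
        Restored image from the last ``fit``.
    trace_ : SolveTrace
        Objective and step-norm history.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        psf: Optional[PSF] = None,
        psf_length: float = 30.0,
        psf_angle: float = 60.0,
        boundary: str = "circular",
        step_size: float = 0.001,
        reg_weight: float = 0.3,
        regularizer: str = "l1",
        max_iters: int = 500,
        rel_tol: float = 1e-6,
        trace_metrics: bool = False,
    ):
        self.psf = psf
        self.psf_length = psf_length
        self.psf_angle = psf_angle
        self.boundary = boundary
        self.step_size = step_size
        self.reg_weight = reg_weight
        self.regularizer = regularizer
        self.max_iters = max_iters
        self.rel_tol = rel_tol
        self.trace_metrics = trace_metrics

    def _config(self) -> SolverConfig:
        return SolverConfig(
            step_size=self.step_size,
            reg_weight=self.reg_weight,
            regularizer=self.regularizer,
            max_iters=self.max_iters,
            rel_tol=self.rel_tol,
            trace_metrics=self.trace_metrics,
        )

    def _psf(self) -> PSF:
        if self.psf is None:
            return make_motion_psf(self.psf_length, self.psf_angle)
        if isinstance(self.psf, PSF):
            return self.psf
        k = np.asarray(self.psf, dtype=np.float64)
        return PSF(kernel=k, length=float("nan"), angle=float("nan"))

    def fit(self, X, y=None, x0=None):
        """Solve the restoration problem for the degraded image ``X``.

        ``X`` may be a raw 2-D observed image or a
        :class:`~fbfdeblur.degradation.DegradedObservation` (in which case
        its recorded PSF and boundary are used unless overridden by ``psf``).
        """
        if isinstance(X, DegradedObservation):
            obs = X
            psf = self._psf() if self.psf is not None else obs.psf
            boundary = self.boundary
        else:
            obs = DegradedObservation(
                observed=as_image(X, name="observed"),
                psf=self._psf(),
                spec=DegradationSpec(
                    psf_length=self.psf_length,
                    psf_angle=self.psf_angle,
                    noise_family="none",
                    noise_level=0.0,
                    boundary=self.boundary,
                ),
            )
            psf = obs.psf
            boundary = self.boundary
        problem = RestorationProblem(obs, psf=psf, boundary=boundary)
        result = tseng_solve(problem, self._config(), x0=x0)
        self.image_ = result.restored
        self.trace_ = result.trace
        self.n_iter_ = result.trace.iterations_run
        self.converged_ = result.trace.converged
        return self

    def transform(self, X) -> np.ndarray:
        """Restore ``X``; equivalent to ``fit(X).image_``."""
        return self.fit(X).image_
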