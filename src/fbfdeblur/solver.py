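"""Tseng forward-backward-forward splitting for l1-regularized deconvolution.

Solves

    min_x  1/2 ||D x - y||^2 + mu * g(x),

with ``D`` a known blur operator, ``y`` the degraded observation and ``g``
either the elementwise l1 norm (default) or the Euclidean norm. A minimizer
is a zero of the monotone inclusion ``0 in grad f(x) + mu * dg(x)``, which
the iteration approaches with a forward (gradient) step, a backward
(proximal) step and a second forward correction step:

    w_k     = prox_{lam*mu*g}(x_k - lam * grad f(x_k))
    x_{k+1} = w_k - lam * (grad f(w_k) - grad f(x_k)).

Unlike plain proximal gradient, the correction step makes the iteration
convergent for any Lipschitz-continuous gradient with step lam < 1/L and
Fejer-monotone with respect to the solution set. The gradient is
``grad f(x) = D^T (D x - y)``, so L = ||D||^2 <= 1 for a unit-sum kernel
under circular boundaries and the reference step lam = 0.001 is always safe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from ._validation import as_image, check_same_shape
from .degradation import BlurOperator, DegradedObservation, PSF
from .exceptions import DivergenceError, InvalidParameterError

logger = logging.getLogger(__name__)

REGULARIZERS = ("l1", "euclidean_norm")

#: guard for the relative-change denominator on (near-)zero iterates
_REL_EPS = 1e-12

#: objective may not exceed 10x its running minimum
_DIVERGENCE_FACTOR = 10.0

#: progress is logged every this many iterations
_LOG_EVERY = 50


@dataclass(frozen=True)
class SolverConfig:
    """Configuration of the splitting iteration.

    ``step_size`` is the step lam (must satisfy lam * L < 1, checked at solve
    time against the operator-norm bound of D) and ``reg_weight`` the
    regularization weight mu; the defaults lam = 0.001, mu = 0.3 are the
    reference settings for [0, 1]-scaled images.
    """

    step_size: float = 0.001
    reg_weight: float = 0.3
    regularizer: str = "l1"
    max_iters: int = 500
    rel_tol: float = 1e-6
    trace_metrics: bool = False

    def __post_init__(self):
        if self.step_size <= 0:
            raise InvalidParameterError("step_size must be > 0")
        if self.reg_weight < 0:
            raise InvalidParameterError("reg_weight must be >= 0")
        if self.regularizer not in REGULARIZERS:
            raise InvalidParameterError(
                f"regularizer must be one of {REGULARIZERS}, got {self.regularizer!r}"
            )
        if self.max_iters < 1:
            raise InvalidParameterError("max_iters must be >= 1")
        if self.rel_tol < 0:
            raise InvalidParameterError("rel_tol must be >= 0")


class RestorationProblem:
    """The data-fit side of the problem: observation ``y`` and operator ``D``.

    ``psf`` and ``boundary`` default to those recorded in the observation,
    which for simulated data are exactly the ones that produced it.
    """

    def __init__(
        self,
        observation: DegradedObservation,
        psf: Optional[PSF] = None,
        boundary: Optional[str] = None,
    ):
        self.observation = observation
        self.psf = psf if psf is not None else observation.psf
        self.boundary = boundary if boundary is not None else observation.spec.boundary
        self.operator = BlurOperator(
            self.psf.kernel, observation.observed.shape, self.boundary
        )

    @property
    def observed(self) -> np.ndarray:
        return self.observation.observed


def _reg_value(x: np.ndarray, regularizer: str) -> float:
    if regularizer == "l1":
        return float(np.abs(x).sum())
    if regularizer == "euclidean_norm":
        return float(np.linalg.norm(x))
    raise InvalidParameterError(f"unknown regularizer {regularizer!r}")


def objective(
    x,
    problem: RestorationProblem,
    reg_weight: float,
    regularizer: str = "l1",
) -> float:
    """Evaluate F(x) = 1/2 ||D x - y||^2 + mu * g(x)."""
    x = as_image(x)
    check_same_shape(x, problem.observed, names=("x", "observed"))
    residual = problem.operator.forward(x) - problem.observed
    return 0.5 * float(np.sum(residual**2)) + reg_weight * _reg_value(x, regularizer)


def grad_f(x, problem: RestorationProblem) -> np.ndarray:
    """Gradient of the data-fit term: D^T (D x - y)."""
    x = as_image(x)
    check_same_shape(x, problem.observed, names=("x", "observed"))
    return problem.operator.adjoint(problem.operator.forward(x) - problem.observed)


def prox_l1(v, threshold: float) -> np.ndarray:
    """Soft-thresholding, the resolvent of t * d||.||_1."""
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    v = np.asarray(v, dtype=np.float64)
    return np.sign(v) * np.maximum(np.abs(v) - threshold, 0.0)


def prox_euclidean_norm(v, threshold: float) -> np.ndarray:
    """Block soft-thresholding, the resolvent of t * d||.||_2.

    Shrinks the whole array toward zero along its own direction; returns
    exactly zero when ||v|| <= threshold.
    """
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    v = np.asarray(v, dtype=np.float64)
    norm = float(np.linalg.norm(v))
    if norm <= threshold:
        return np.zeros_like(v)
    return v * (1.0 - threshold / norm)


def _prox(v: np.ndarray, threshold: float, regularizer: str) -> np.ndarray:
    if regularizer == "l1":
        return prox_l1(v, threshold)
    return prox_euclidean_norm(v, threshold)


def tseng_step(x_k, problem: RestorationProblem, config: SolverConfig):
    """One forward-backward-forward step; returns (w_k, x_{k+1}).

    Costs exactly two gradient evaluations and one proximal evaluation.
    """
    lam = config.step_size
    g_x = grad_f(x_k, problem)
    w_k = _prox(x_k - lam * g_x, lam * config.reg_weight, config.regularizer)
    g_w = grad_f(w_k, problem)
    x_next = w_k - lam * (g_w - g_x)
    return w_k, x_next


@dataclass
class SolveTrace:
    """Per-iteration diagnostics of a solve."""

    objective: List[float] = field(default_factory=list)
    step_norm: List[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False
    iterates_kept: Optional[List[np.ndarray]] = None
    metrics: Optional[dict] = None  # {"ssim": [...], "isnr": [...]} when traced


@dataclass
class RestorationResult:
    restored: np.ndarray
    trace: SolveTrace
    config: SolverConfig


def tseng_solve(
    problem: RestorationProblem,
    config: Optional[SolverConfig] = None,
    x0=None,
    keep_iterates: bool = False,
    callback: Optional[Callable[[int, np.ndarray], None]] = None,
) -> RestorationResult:
    """Run the forward-backward-forward iteration to (approximate) convergence.

    ``x0`` defaults to the observed image. Stops when the relative step norm
    ``||x_{k+1} - x_k|| / max(||x_k||, 1e-12)`` falls below ``rel_tol`` or
    after ``max_iters`` iterations. Fully deterministic.

    Raises
    ------
    DivergenceError
        If the objective grows beyond 10x its running minimum, which for a
        valid step size cannot happen.
    InvalidParameterError
        If ``step_size * L >= 1`` for the operator-norm bound L of D^T D.
    """
    config = config or SolverConfig()
    lam = config.step_size
    lipschitz = problem.operator.lipschitz_bound()
    if lam * lipschitz >= 1.0:
        raise InvalidParameterError(
            f"step_size {lam} violates step_size * L < 1 (L ~= {lipschitz:.6g})"
        )

    x = as_image(x0) if x0 is not None else problem.observed.copy()
    check_same_shape(x, problem.observed, names=("x0", "observed"))

    trace = SolveTrace(iterates_kept=[x.copy()] if keep_iterates else None)
    if config.trace_metrics and problem.observation.clean is not None:
        trace.metrics = {"ssim": [], "isnr": []}
        from . import metrics as _metrics  # local import: metrics is a leaf module

    best = np.inf
    for k in range(1, config.max_iters + 1):
        _, x_next = tseng_step(x, problem, config)
        step = float(np.linalg.norm(x_next - x))
        obj = objective(x_next, problem, config.reg_weight, config.regularizer)
        trace.objective.append(obj)
        trace.step_norm.append(step)
        if trace.iterates_kept is not None:
            trace.iterates_kept.append(x_next.copy())
        if trace.metrics is not None:
            clean = problem.observation.clean
            trace.metrics["ssim"].append(_metrics.ssim(clean, x_next))
            trace.metrics["isnr"].append(
                _metrics.isnr(clean, problem.observed, x_next)
            )
        if callback is not None:
            callback(k, x_next)
        if k % _LOG_EVERY == 0:
            logger.info("iter %d  objective %.6e  step %.3e", k, obj, step)

        best = min(best, obj)
        if obj > _DIVERGENCE_FACTOR * best and obj > best + _REL_EPS:
            raise DivergenceError(
                f"objective {obj:.6g} exceeded 10x its running minimum "
                f"{best:.6g} at iteration {k}; step size likely too large"
            )
        denom = max(float(np.linalg.norm(x)), _REL_EPS)
        x = x_next
        trace.iterations_run = k
        if step / denom < config.rel_tol:
            trace.converged = True
            break

    return RestorationResult(restored=x, trace=trace, config=config)


def optimality_residual(x, problem: RestorationProblem, config: SolverConfig) -> float:
    """Fixed-point residual ||x - prox_{lam*mu*g}(x - lam*grad f(x))|| / lam.

    Zero exactly when 0 is in grad f(x) + mu * dg(x), i.e. when x solves the
    inclusion; small values certify approximate optimality.
    """
    lam = config.step_size
    g = grad_f(x, problem)
    p = _prox(np.asarray(x) - lam * g, lam * config.reg_weight, config.regularizer)
    return float(np.linalg.norm(np.asarray(x) - p)) / lam
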