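"""Bounded nonlinear least-squares baseline estimator.

The reference method against which dictionary matching is compared: each
tissue curve is fit by trust-region-reflective least squares over
(AF, DV, MTT) directly, with box bounds AF, DV in [0, 1] and MTT in
[0.0001, 100] s, initial guess (0.2, 0.2, 10), and deliberately loose
termination tolerances (step 1e-2, function 1e-3, gradient 1e-1) matching a
typical clinical processing configuration.

Tolerance semantics are mapped onto :func:`scipy.optimize.least_squares`:
step tolerance -> ``xtol`` (relative change in the parameter vector),
function tolerance -> ``ftol`` (relative change in the cost), gradient
tolerance -> ``gtol`` (first-order optimality).  The trust region is
defined in Jacobian-scaled space (``x_scale='jac'``), mirroring the
affine scaling the reference trust-region-reflective implementation
applies internally; without it the very loose gradient tolerance halts
far from the optimum for slow-kinetics (long MTT) curves.  The Jacobian
is computed by forward finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .model import PerfusionParams, check_times, exp_conv, params_to_rates, _shift_input
from .inputs import InputFunctions

__all__ = [
    "FitConfig",
    "FitResult",
    "default_fit_config",
    "fit_curve",
    "CurveFitEstimator",
]


@dataclass(frozen=True)
class FitConfig:
    """Curve-fitting configuration (bounds, initial guess, tolerances)."""

    bounds_lower: tuple = (0.0, 0.0, 1e-4)  # AF, DV, MTT
    bounds_upper: tuple = (1.0, 1.0, 100.0)
    initial_guess: tuple = (0.2, 0.2, 10.0)
    step_tolerance: float = 1e-2
    function_tolerance: float = 1e-3
    gradient_tolerance: float = 1e-1
    max_iterations: int = 300

    def __post_init__(self):
        lo, hi, x0 = map(np.asarray, (self.bounds_lower, self.bounds_upper, self.initial_guess))
        if np.any(lo >= hi):
            raise ValueError("lower bounds must lie below upper bounds")
        if np.any(x0 < lo) or np.any(x0 > hi):
            raise ValueError("initial guess must lie within bounds")

    def tightened(self, tol: float = 1e-10) -> "FitConfig":
        """Copy with all tolerances set to ``tol`` (high-precision reference)."""
        return replace(
            self, step_tolerance=tol, function_tolerance=tol, gradient_tolerance=tol
        )


def default_fit_config() -> FitConfig:
    """The reference configuration: bounds [0,1]/[0,1]/[1e-4,100], x0 (0.2, 0.2, 10)."""
    return FitConfig()


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-curve fit."""

    params: PerfusionParams
    residual_norm: float
    converged: bool
    n_iterations: int


class _ModelEvaluator:
    """Precomputes shifted plasma inputs so repeated evaluations are cheap."""

    def __init__(self, inputs: InputFunctions, times: np.ndarray | None = None):
        self.times = check_times(inputs.times if times is None else times)
        ca, cp = inputs.plasma()
        if inputs.times.shape != self.times.shape or not np.allclose(inputs.times, self.times):
            raise ValueError("input functions must be sampled on the fitting time grid")
        self.ca = _shift_input(self.times, ca, inputs.tau_a)
        self.cp = _shift_input(self.times, cp, inputs.tau_p)

    def __call__(self, af: float, dv: float, mtt: float) -> np.ndarray:
        k2 = 1.0 / mtt
        u = dv * k2 * (af * self.ca + (1.0 - af) * self.cp)
        return exp_conv(self.times, u, k2)


def fit_curve(
    curve: np.ndarray,
    inputs: InputFunctions,
    cfg: FitConfig | None = None,
    times: np.ndarray | None = None,
    _evaluator: _ModelEvaluator | None = None,
) -> FitResult:
    """Fit (AF, DV, MTT) to one tissue concentration curve.

    Minimizes the sum of squared residuals between the curve and the
    dual-input single-compartment model, within bounds, starting from the
    configured initial guess.  Deterministic for fixed inputs and config.
    """
    if cfg is None:
        cfg = default_fit_config()
    curve = np.asarray(curve, dtype=float)
    if not np.all(np.isfinite(curve)):
        raise ValueError("curve contains non-finite values")
    ev = _evaluator if _evaluator is not None else _ModelEvaluator(inputs, times)
    if curve.shape != ev.times.shape:
        raise ValueError("curve length must match the time grid")

    def residuals(x):
        return ev(x[0], x[1], x[2]) - curve

    sol = least_squares(
        residuals,
        x0=np.asarray(cfg.initial_guess, dtype=float),
        bounds=(np.asarray(cfg.bounds_lower), np.asarray(cfg.bounds_upper)),
        method="trf",
        x_scale="jac",
        xtol=cfg.step_tolerance,
        ftol=cfg.function_tolerance,
        gtol=cfg.gradient_tolerance,
        max_nfev=cfg.max_iterations * 4,
    )
    params = PerfusionParams(af=float(sol.x[0]), dv=float(sol.x[1]), mtt=float(sol.x[2]))
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.status > 0),
        n_iterations=int(sol.nfev),
    )


class CurveFitEstimator(BaseEstimator):
    """Per-curve nonlinear least-squares perfusion estimator.

    scikit-learn-style counterpart of :class:`~liverperf.dictionary.DictionaryMatcher`:
    ``fit`` prepares the (delay-shifted, plasma-corrected) input functions;
    ``predict`` maps an (m, t) array of tissue concentration curves to an
    (m, 3) array of (AF, DV, MTT) estimates by independent bounded fits.
    """

    def __init__(
        self,
        inputs: InputFunctions | None = None,
        times=None,
        config: FitConfig | None = None,
    ):
        self.inputs = inputs
        self.times = times
        self.config = config

    def fit(self, X=None, y=None):
        if self.inputs is None:
            raise ValueError("CurveFitEstimator requires `inputs`")
        self.config_ = self.config if self.config is not None else default_fit_config()
        self.evaluator_ = _ModelEvaluator(self.inputs, self.times)
        return self

    def fit_results(self, X) -> list[FitResult]:
        """One :class:`FitResult` per curve row."""
        if not hasattr(self, "evaluator_"):
            raise RuntimeError("call fit() before predicting")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return [
            fit_curve(row, self.inputs, self.config_, _evaluator=self.evaluator_)
            for row in X
        ]

    def predict(self, X) -> np.ndarray:
        """(m, 3) array of (AF, DV, MTT) estimates."""
        return np.array([r.params.as_array() for r in self.fit_results(X)])
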