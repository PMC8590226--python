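"""Individual curve fitting and the height-to-weight transform.

Weight measurements carry far larger day-to-day variation than height, so a
direct six-parameter weight fit overfits.  The pipeline therefore:

1. fits the six QEPS parameters to each subject's *height* series
   (:func:`fit_height`);
2. estimates, per sex, four population-level coefficients that map the
   height component scales to kg^0.5 component scales
   (:func:`estimate_transform`), keeping pubertal timing and tempo from the
   height fit;
3. absorbs the remaining individual variation in a single constitutional
   weight-height factor, WHF (:func:`fit_whf`): the individual sqrt-weight
   curve is ``(1 + WHF)`` times the height-predicted one, with WHF = 0 a
   normal, WHF > 0 a heavier, and WHF < 0 a leaner body constitution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares, lsq_linear, nnls

from .qeps_model import (
    QEPSParams,
    ShapeConstants,
    ValidationError,
    basis,
    eval_components,
)

__all__ = [
    "Measurement",
    "TransformCoefficients",
    "WHFResult",
    "FitResult",
    "FitOptions",
    "InsufficientCoverageError",
    "DegenerateTransformError",
    "DegeneratePredictionError",
    "fit_height",
    "estimate_transform",
    "predict_weight",
    "fit_whf",
]

logger = logging.getLogger(__name__)


class InsufficientCoverageError(ValueError):
    """Too few or ill-spanned measurements to identify the six parameters."""


class DegenerateTransformError(ValueError):
    """Transform design matrix is rank deficient (e.g. no pubertal signal)."""


class DegeneratePredictionError(ValueError):
    """Predicted weight curve is identically zero; WHF undefined."""


@dataclass(frozen=True)
class Measurement:
    """One observed visit: decimal age with height and/or weight."""

    subject_id: str
    sex: str
    age: float
    height: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError("age must be non-negative")
        if self.height is not None and not (30.0 < self.height < 230.0):
            raise ValidationError(f"implausible height {self.height} cm")
        if self.weight is not None and not (1.0 < self.weight < 250.0):
            raise ValidationError(f"implausible weight {self.weight} kg")


@dataclass(frozen=True)
class TransformCoefficients:
    """Per-sex linear map from height to sqrt-weight component scales.

    ``c_X^weight = alpha_X * c_X^height`` for X in {Q, E, P, S}; units are
    kg^0.5 per cm.  Timing and tempo are shared between traits.
    """

    alpha_Q: float
    alpha_E: float
    alpha_P: float
    alpha_S: float

    def __post_init__(self) -> None:
        vals = (self.alpha_Q, self.alpha_E, self.alpha_P, self.alpha_S)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("transform coefficients must be finite")
        if min(self.alpha_Q, self.alpha_E, self.alpha_P) < 0:
            raise ValidationError("alpha_Q, alpha_E, alpha_P must be non-negative")


@dataclass(frozen=True)
class WHFResult:
    """Fitted weight-height factor and residual RMSE in kg^0.5."""

    whf: float
    rmse: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.whf > -1.0):
            raise ValidationError("WHF must exceed -1")


@dataclass(frozen=True)
class FitResult:
    params: QEPSParams
    rmse: float
    n_points: int
    converged: bool


@dataclass(frozen=True)
class FitOptions:
    """Fitting controls.

    ``theta_starts`` are the deterministic multi-start pubertal timings; a
    moment-based guess (age of maximal observed velocity) is always added.
    Observations with absolute studentized residual above
    ``outlier_threshold`` are dropped in a single re-fit pass.
    """

    theta_starts: tuple[float, ...] = (9.0, 11.0, 13.0, 15.0)
    theta_bounds: tuple[float, float] = (7.0, 18.0)
    sigma_bounds: tuple[float, float] = (0.3, 3.0)
    min_points: int = 6
    min_first_age: float = 2.0
    min_last_age: float = 16.0
    min_late_points: int = 2
    late_age: float = 13.0
    outlier_threshold: float = 4.0


# --- height fitting ---------------------------------------------------------


def _coverage_check(ages: np.ndarray, opts: FitOptions) -> None:
    if ages.size < opts.min_points:
        raise InsufficientCoverageError(
            f"insufficient longitudinal coverage: {ages.size} points "
            f"(need >= {opts.min_points})"
        )
    if ages.min() > opts.min_first_age or ages.max() < opts.min_last_age:
        raise InsufficientCoverageError(
            "insufficient longitudinal coverage: series must span ages "
            f"{opts.min_first_age}-{opts.min_last_age}"
        )
    if np.sum(ages > opts.late_age) < opts.min_late_points:
        raise InsufficientCoverageError(
            "insufficient longitudinal coverage: need >= "
            f"{opts.min_late_points} points after age {opts.late_age}"
        )


def _scales_given_timing(theta: float, sigma: float, ages: np.ndarray,
                         y: np.ndarray, shape: ShapeConstants) -> tuple[np.ndarray, float]:
    """Non-negative least-squares solve for (c_Q, c_E, c_P, c_S)."""
    Qb, Eb, Pb, Sb = basis(shape, theta, sigma, ages)
    A = np.column_stack([Qb, Eb, Pb, -Sb])
    c, rnorm = nnls(A, y)
    return c, rnorm


def _moment_theta_guess(ages: np.ndarray, y: np.ndarray,
                        opts: FitOptions) -> float | None:
    """Age of maximal observed velocity inside the plausible pubertal window."""
    order = np.argsort(ages)
    a, h = ages[order], y[order]
    da = np.diff(a)
    ok = da > 0.05
    if not ok.any():
        return None
    mid = (a[:-1] + a[1:])[ok] / 2.0
    vel = (np.diff(h) / da)[ok]
    window = (mid >= 8.0) & (mid <= 16.0)
    if not window.any():
        return None
    return float(np.clip(mid[window][np.argmax(vel[window])],
                         opts.theta_bounds[0] + 0.5, opts.theta_bounds[1] - 0.5))


def _full_residual(x: np.ndarray, ages: np.ndarray, y: np.ndarray,
                   shape: ShapeConstants) -> np.ndarray:
    cQ, cE, cP, cS, theta, sigma = x
    Qb, Eb, Pb, Sb = basis(shape, theta, sigma, ages)
    return cQ * Qb + cE * Eb + cP * Pb - cS * Sb - y


def _fit_once(ages: np.ndarray, y: np.ndarray, shape: ShapeConstants,
              opts: FitOptions) -> tuple[np.ndarray, float, bool]:
    """Multi-start variable-projection fit followed by a six-parameter polish."""
    starts = list(opts.theta_starts)
    guess = _moment_theta_guess(ages, y, opts)
    if guess is not None:
        starts.append(guess)

    best: tuple[float, float, np.ndarray] | None = None  # (ssr, theta0, x)
    for theta0 in starts:
        def vp_resid(ts: np.ndarray) -> np.ndarray:
            c, _ = _scales_given_timing(ts[0], ts[1], ages, y, shape)
            Qb, Eb, Pb, Sb = basis(shape, ts[0], ts[1], ages)
            return c[0] * Qb + c[1] * Eb + c[2] * Pb - c[3] * Sb - y

        sol = least_squares(
            vp_resid, x0=[theta0, 1.0],
            bounds=([opts.theta_bounds[0], opts.sigma_bounds[0]],
                    [opts.theta_bounds[1], opts.sigma_bounds[1]]),
            diff_step=1e-4, max_nfev=200,
        )
        theta, sigma = sol.x
        c, _ = _scales_given_timing(theta, sigma, ages, y, shape)
        x0 = np.concatenate([c, [theta, sigma]])
        polish = least_squares(
            _full_residual, x0=x0, args=(ages, y, shape),
            bounds=([0.0, 0.0, 0.0, 0.0, opts.theta_bounds[0], opts.sigma_bounds[0]],
                    [np.inf] * 4 + [opts.theta_bounds[1], opts.sigma_bounds[1]]),
            max_nfev=400,
        )
        ssr = 2.0 * polish.cost
        # ties broken by smallest fitted theta_P
        key = (round(ssr, 12), polish.x[4])
        if best is None or key < (round(best[0], 12), best[2][4]):
            best = (ssr, theta0, polish.x)
    assert best is not None
    ssr, _, x = best
    return x, ssr, True


def fit_height(measurements: Iterable[Measurement], shape: ShapeConstants,
               options: FitOptions | None = None) -> FitResult:
    """Fit the six individual QEPS parameters to one subject's heights.

    Deterministic: multi-starts are a fixed grid plus a moment-based guess,
    with ties broken by the smallest pubertal timing.  One robustness pass
    drops observations with absolute studentized residual above the
    configured threshold and refits.

    Raises
    ------
    InsufficientCoverageError
        Fewer than the minimum number of height points, or the series does
        not span early childhood to late adolescence.
    """
    opts = options or FitOptions()
    pts = [(m.age, m.height) for m in measurements if m.height is not None]
    ages = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    _coverage_check(ages, opts)

    x, ssr, converged = _fit_once(ages, y, shape, opts)
    resid = _full_residual(x, ages, y, shape)
    scale = np.sqrt(np.mean(resid**2))
    if scale > 0:
        keep = np.abs(resid / scale) <= opts.outlier_threshold
        if keep.sum() >= opts.min_points and not keep.all():
            try:
                _coverage_check(ages[keep], opts)
            except InsufficientCoverageError:
                pass
            else:
                x, ssr, converged = _fit_once(ages[keep], y[keep], shape, opts)
                resid = _full_residual(x, ages[keep], y[keep], shape)
                ages, y = ages[keep], y[keep]

    params = QEPSParams(c_Q=x[0], c_E=x[1], c_P=x[2], c_S=x[3],
                        theta_P=x[4], sigma_P=x[5], trait="height")
    rmse = float(np.sqrt(np.mean(resid**2)))
    logger.info("fit_height: n=%d rmse=%.4f theta_P=%.3f", ages.size,
                rmse, params.theta_P)
    return FitResult(params=params, rmse=rmse, n_points=int(ages.size),
                     converged=converged)


# --- height -> weight transform --------------------------------------------


def estimate_transform(
    subjects: Sequence[tuple[QEPSParams, Sequence[tuple[float, float]]]],
    shape: ShapeConstants,
    min_subjects: int = 30,
    min_weight_points: int = 6,
) -> TransformCoefficients:
    """Estimate the per-sex height-to-weight transform coefficients.

    Parameters
    ----------
    subjects
        Pairs of (fitted height params, weight observations) where each
        observation is an ``(age, weight_kg)`` tuple.
    shape
        Sex-specific shape constants used for the height fits.

    The coefficients minimise, over all subjects and visits jointly, the sum
    of squared differences between observed sqrt-weight and the linear
    combination ``a_Q c_Q Q + a_E c_E E + a_P c_P P - a_S c_S S`` of the
    subject's scaled height components.
    """
    rows, targets = [], []
    n_used = 0
    for params, wobs in subjects:
        wobs = [(a, w) for a, w in wobs if w is not None]
        if len(wobs) < min_weight_points:
            continue
        n_used += 1
        ages = np.array([a for a, _ in wobs], dtype=float)
        w = np.array([w for _, w in wobs], dtype=float)
        Qb, Eb, Pb, Sb = basis(shape, params.theta_P, params.sigma_P, ages)
        rows.append(np.column_stack([params.c_Q * Qb, params.c_E * Eb,
                                     params.c_P * Pb, -params.c_S * Sb]))
        targets.append(np.sqrt(w))
    if not rows:
        raise DegenerateTransformError("no subjects with sufficient weight data")
    if n_used < min_subjects:
        warnings.warn(
            f"transform estimated from only {n_used} subjects "
            f"(< {min_subjects}); coefficients may have wide variance",
            stacklevel=2,
        )
    A = np.vstack(rows)
    b = np.concatenate(targets)
    scale = np.linalg.norm(A, axis=0)
    if np.any(scale < 1e-10 * max(scale.max(), 1.0)):
        raise DegenerateTransformError(
            "degenerate transform: a component column carries no signal"
        )
    rank = np.linalg.matrix_rank(A)
    if rank < 4:
        raise DegenerateTransformError(
            "degenerate transform: design matrix is rank deficient"
        )
    # non-negative so the mapped weight scales stay valid QEPS parameters
    sol = lsq_linear(A, b, bounds=(0.0, np.inf)).x
    return TransformCoefficients(alpha_Q=float(sol[0]), alpha_E=float(sol[1]),
                                 alpha_P=float(sol[2]), alpha_S=float(sol[3]))


def predict_weight(params_height: QEPSParams,
                   coefs: TransformCoefficients) -> QEPSParams:
    """Map a height fit to the corresponding sqrt-weight parameter set.

    Component scales are multiplied by the transform coefficients; pubertal
    timing and tempo are copied unchanged.
    """
    return QEPSParams(
        c_Q=coefs.alpha_Q * params_height.c_Q,
        c_E=coefs.alpha_E * params_height.c_E,
        c_P=coefs.alpha_P * params_height.c_P,
        c_S=coefs.alpha_S * params_height.c_S,
        theta_P=params_height.theta_P,
        sigma_P=params_height.sigma_P,
        trait="weight",
    )


def fit_whf(weight_obs: Sequence[tuple[float, float]],
            predicted: QEPSParams, shape: ShapeConstants,
            min_points: int = 4) -> WHFResult:
    """Fit the constitutional weight-height factor for one subject.

    Minimises ``sum (sqrt(w_obs) - (1 + WHF) * w_hat(age))^2`` over WHF,
    which has the closed form ``sum(w_hat * sqrt(w_obs)) / sum(w_hat^2) - 1``.
    The individual weight curve is ``(1 + WHF) * w_hat`` in kg^0.5.
    """
    obs = [(a, w) for a, w in weight_obs if w is not None]
    if len(obs) < min_points:
        raise InsufficientCoverageError(
            f"need >= {min_points} weight points to estimate WHF, got {len(obs)}"
        )
    ages = np.array([a for a, _ in obs], dtype=float)
    sw = np.sqrt(np.array([w for _, w in obs], dtype=float))
    what = eval_components(predicted, shape, ages).total
    denom = float(np.dot(what, what))
    if denom <= 0:
        raise DegeneratePredictionError("predicted weight curve is zero")
    whf = float(np.dot(what, sw) / denom) - 1.0
    resid = sw - (1.0 + whf) * what
    return WHFResult(whf=whf, rmse=float(np.sqrt(np.mean(resid**2))),
                     n_points=len(obs))
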