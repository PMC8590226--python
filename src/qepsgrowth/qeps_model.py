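"""Shape-invariant QEPS growth functions and derived pubertal landmarks.

The QEPS model describes growth from conception to adulthood as the sum of
four shape-invariant functions: a Quadratic (Q) and an Exponential (E)
component that arise before birth and together carry basic growth, a
puberty-specific logistic component (P), and a Stop function (S) that is
subtracted to end growth:

    total(t) = c_Q * Q(t) + c_E * E(t) + c_P * P(t) - c_S * S(t)
    basic(t) = c_Q * Q(t) + c_E * E(t)              - c_S * S(t)

Each basic function rises from 0 to an asymptote of 1, so the individual
scale parameters are expressed directly in trait units: cm for height, and
kg^0.5 for weight.  The square-root scale is used for weight because the
four components only combine additively on that scale; in kg the additivity
is lost.

Six parameters are individual (four scales plus pubertal timing ``theta_P``
and tempo ``sigma_P``); the remaining constants are population-level shape
constants shared within a sex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ModelError",
    "ValidationError",
    "NoPubertalComponentError",
    "ShapeConstants",
    "QEPSParams",
    "DerivedFeatures",
    "Components",
    "DEFAULT_SHAPE",
    "MAX_AGE",
    "eval_components",
    "velocity",
    "age_at_p_fraction",
    "age_p5",
    "age_at_peak_velocity",
    "derived_features",
    "sqrtkg_to_kg",
    "kg_to_sqrtkg",
    "is_monotone",
]

MAX_AGE = 40.0  # years; every component is numerically saturated well before


class ModelError(Exception):
    """Base class for model-layer errors."""


class ValidationError(ModelError, ValueError):
    """A parameter set or argument violates its invariants."""


class NoPubertalComponentError(ModelError):
    """Operation requires a pubertal component but c_P = 0."""


@dataclass(frozen=True)
class ShapeConstants:
    """Population-level shape constants of the QEPS basis (per sex).

    Parameters
    ----------
    t_conception : float
        Offset of conception before birth, in years (negative).
    T_Q : float
        Age in years at which the quadratic basic function reaches its
        plateau of 1.
    tau_E : float
        Time constant of the exponential basic function, in years.
    kappa_S : float
        Offset of the stop-function midpoint after pubertal midpoint, in
        units of the pubertal tempo ``sigma_P``.
    """

    t_conception: float = -0.75
    T_Q: float = 17.0
    tau_E: float = 0.6
    kappa_S: float = 6.0

    def __post_init__(self) -> None:
        if not (self.T_Q > 0):
            raise ValidationError("T_Q must be positive")
        if not (self.tau_E > 0):
            raise ValidationError("tau_E must be positive")
        if not (self.kappa_S > 0):
            raise ValidationError("kappa_S must be positive")
        if not (self.t_conception < 0):
            raise ValidationError("t_conception must precede birth (be negative)")


#: Default shape constants per sex ("F"/"M"); configurable, not literature values.
DEFAULT_SHAPE: dict[str, ShapeConstants] = {
    "F": ShapeConstants(T_Q=17.0),
    "M": ShapeConstants(T_Q=19.0),
}


@dataclass(frozen=True)
class QEPSParams:
    """The six individual QEPS parameters for one subject and one trait.

    Scales ``c_Q``..``c_S`` are in cm for height and kg^0.5 for weight;
    ``theta_P`` is the pubertal midpoint age in years and ``sigma_P`` the
    pubertal tempo in years.
    """

    c_Q: float
    c_E: float
    c_P: float
    c_S: float
    theta_P: float
    sigma_P: float
    trait: str = "height"

    def __post_init__(self) -> None:
        for name in ("c_Q", "c_E", "c_P", "c_S"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValidationError(f"{name} must be finite and non-negative")
        if not np.isfinite(self.theta_P):
            raise ValidationError("theta_P must be finite")
        if not (np.isfinite(self.sigma_P) and self.sigma_P > 0):
            raise ValidationError("sigma_P must be positive")
        if self.trait not in ("height", "weight"):
            raise ValidationError("trait must be 'height' or 'weight'")

    def with_trait(self, trait: str) -> "QEPSParams":
        return replace(self, trait=trait)


@dataclass(frozen=True)
class DerivedFeatures:
    """Pubertal landmarks derived from a fitted parameter set."""

    Pmax: float        # asymptotic puberty-specific gain, trait units
    AgeP5: float       # age at 5% of Pmax, years (spurt-onset landmark)
    TPHV: float        # age at peak velocity of the total curve, years
    adult_size: float  # total curve evaluated at MAX_AGE, trait units


class Components(NamedTuple):
    """Scaled component curves evaluated on an age grid (trait units)."""

    Q: np.ndarray
    E: np.ndarray
    P: np.ndarray
    S: np.ndarray
    total: np.ndarray
    basic: np.ndarray


def _logistic(x: np.ndarray) -> np.ndarray:
    # numerically stable on both tails
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def basis(shape: ShapeConstants, theta_P: float, sigma_P: float,
          ages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unit-scale basic functions (Q, E, P, S), each rising from 0 to 1.

    Q rises quadratically from conception and plateaus at ``T_Q``; E is a
    saturating exponential from conception; P and S are logistics with the
    common tempo ``sigma_P``, S delayed by ``kappa_S * sigma_P`` years.
    """
    t = np.asarray(ages, dtype=float)
    tau = (t - shape.t_conception) / (shape.T_Q - shape.t_conception)
    tau = np.clip(tau, 0.0, 1.0)
    Q = 2.0 * tau - tau * tau
    E = 1.0 - np.exp(-np.clip(t - shape.t_conception, 0.0, None) / shape.tau_E)
    P = _logistic((t - theta_P) / sigma_P)
    S = _logistic((t - theta_P - shape.kappa_S * sigma_P) / sigma_P)
    return Q, E, P, S


def _check_ages(ages: np.ndarray, shape: ShapeConstants) -> np.ndarray:
    t = np.atleast_1d(np.asarray(ages, dtype=float))
    if t.size and (t.min() < shape.t_conception - 1e-12 or t.max() > MAX_AGE + 1e-12):
        raise ValidationError(
            f"ages must lie within [{shape.t_conception}, {MAX_AGE}] years"
        )
    return t


def eval_components(params: QEPSParams, shape: ShapeConstants,
                    ages) -> Components:
    """Evaluate the scaled Q, E, P, S curves plus total and basic.

    ``total = Q + E + P - S`` and ``basic = Q + E - S`` hold exactly (to
    machine precision) at every age; all components are individually
    non-decreasing in age.
    """
    t = _check_ages(ages, shape)
    Qb, Eb, Pb, Sb = basis(shape, params.theta_P, params.sigma_P, t)
    Q = params.c_Q * Qb
    E = params.c_E * Eb
    P = params.c_P * Pb
    S = params.c_S * Sb
    return Components(Q=Q, E=E, P=P, S=S, total=Q + E + P - S, basic=Q + E - S)


def velocity(params: QEPSParams, shape: ShapeConstants, ages) -> np.ndarray:
    """Analytic derivative of the total curve, trait units per year."""
    t = _check_ages(ages, shape)
    span = shape.T_Q - shape.t_conception
    tau = (t - shape.t_conception) / span
    dQ = np.where((tau >= 0) & (tau <= 1), 2.0 * (1.0 - tau) / span, 0.0)
    rel = np.clip(t - shape.t_conception, 0.0, None)
    dE = np.exp(-rel / shape.tau_E) / shape.tau_E
    dE = np.where(t >= shape.t_conception, dE, 0.0)
    lp = _logistic((t - params.theta_P) / params.sigma_P)
    dP = lp * (1.0 - lp) / params.sigma_P
    ls = _logistic(
        (t - params.theta_P - shape.kappa_S * params.sigma_P) / params.sigma_P
    )
    dS = ls * (1.0 - ls) / params.sigma_P
    return (params.c_Q * dQ + params.c_E * dE
            + params.c_P * dP - params.c_S * dS)


def age_at_p_fraction(params: QEPSParams, fraction: float) -> float:
    """Age at which the P component reaches ``fraction`` of Pmax.

    Closed form from the logistic basis:
    ``theta_P + sigma_P * ln(fraction / (1 - fraction))``.
    """
    if params.c_P <= 0:
        raise NoPubertalComponentError("c_P = 0: no pubertal component")
    if not (0.0 < fraction < 1.0):
        raise ValidationError("fraction must lie strictly within (0, 1)")
    return params.theta_P + params.sigma_P * math.log(fraction / (1.0 - fraction))


def age_p5(params: QEPSParams) -> float:
    """Onset of the pubertal growth spurt: age at 5% of Pmax (AgeP5)."""
    return age_at_p_fraction(params, 0.05)


def age_at_peak_velocity(params: QEPSParams, shape: ShapeConstants) -> float:
    """Age at peak velocity of the total curve (TPHV for height), years.

    Searches ``theta_P ± 6 sigma_P`` on a dense grid and refines with a
    bounded scalar maximisation to 1e-4 y.  The pubertal peak is an interior
    *local* maximum of velocity: total velocity declines steadily through
    childhood (the quadratic component decelerates), so when the search
    window reaches into childhood the largest interior local maximum — the
    spurt — is returned rather than the high early-childhood velocity at the
    window edge.  If no interior local maximum exists the global argmax over
    the window is used.
    """
    if params.c_P <= 0:
        raise NoPubertalComponentError("c_P = 0: no pubertal component")
    lo = max(shape.t_conception, params.theta_P - 6.0 * params.sigma_P)
    hi = min(MAX_AGE, params.theta_P + 6.0 * params.sigma_P)
    grid = np.linspace(lo, hi, 601)
    v = velocity(params, shape, grid)
    interior = np.flatnonzero((v[1:-1] >= v[:-2]) & (v[1:-1] >= v[2:])) + 1
    if interior.size:
        k = int(interior[np.argmax(v[interior])])
    else:
        k = int(np.argmax(v))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda t: -velocity(params, shape, np.array([t]))[0],
        bounds=(a, b), method="bounded", options={"xatol": 1e-5},
    )
    return float(res.x)


def derived_features(params: QEPSParams, shape: ShapeConstants) -> DerivedFeatures:
    """Pmax, AgeP5, TPHV and adult size for one fitted individual."""
    return DerivedFeatures(
        Pmax=params.c_P,
        AgeP5=age_p5(params),
        TPHV=age_at_peak_velocity(params, shape),
        adult_size=float(eval_components(params, shape, [MAX_AGE]).total[0]),
    )


def sqrtkg_to_kg(value):
    """Convert kg^0.5 to kg (squaring); monotone for non-negative input."""
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValidationError("kg^0.5 values must be non-negative")
    out = v * v
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def kg_to_sqrtkg(value):
    """Convert kg to kg^0.5 (square root); inverse of :func:`sqrtkg_to_kg`."""
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValidationError("kg values must be non-negative")
    out = np.sqrt(v)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def is_monotone(params: QEPSParams, shape: ShapeConstants,
                tol: float = -1e-6) -> bool:
    """True when total velocity never drops below ``tol`` on [0, 25] years.

    A parameter set failing this check describes shrinking growth (the stop
    function overwhelming the pubertal one) and is flagged invalid for
    reference construction.
    """
    grid = np.linspace(0.0, 25.0, 2501)
    return bool(velocity(params, shape, grid).min() >= tol)
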