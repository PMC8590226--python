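"""Seeded synthetic longitudinal cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes for a
longitudinally followed school cohort: per-sex QEPS height parameters drawn
from log-normal/normal distributions, weight produced from height through
the component-wise transform plus an individual constitutional factor (WHF),
an irregular visit schedule from infancy to late adolescence, and additive
measurement noise (larger for weight than height, in kg^0.5).  Ground truth
(parameters, WHF, landmarks) is returned alongside so recovery can be
tested; the truth table is never consumed by the pipeline itself.

Randomness: one global seed; subject ``i`` of a sex uses the dedicated
stream ``default_rng([seed, sex_code, i])`` so any subject is reproducible
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import TransformCoefficients, predict_weight
from .qeps_model import (
    DEFAULT_SHAPE,
    QEPSParams,
    ShapeConstants,
    ValidationError,
    age_at_peak_velocity,
    age_p5,
    eval_components,
)

__all__ = [
    "SexParams",
    "CohortConfig",
    "EffectSpec",
    "DEFAULT_SCHEDULE",
    "default_config",
    "draw_individual",
    "simulate_cohort",
    "make_subgroup_cohort",
]

#: Default visit schedule (years): infancy visits, annual childhood visits,
#: semi-annual adolescent visits, then annual until adult height is reached
#: (late maturers must be followed through their whole spurt) — 25 visits.
DEFAULT_SCHEDULE: tuple[float, ...] = tuple(
    [1.0, 2.0]
    + [float(a) for a in range(3, 10)]
    + [round(10 + 0.5 * k, 1) for k in range(13)]
    + [17.0, 18.0, 19.0]
)


@dataclass(frozen=True)
class SexParams:
    """Per-sex parameter distributions (log-normal: median + SD of log)."""

    c_Q_median: float
    c_E_median: float
    c_P_median: float
    c_S_median: float
    c_Q_logsd: float = 0.04
    c_E_logsd: float = 0.04
    c_P_logsd: float = 0.12
    c_S_logsd: float = 0.30
    theta_P_mean: float = 11.0
    theta_P_sd: float = 1.0
    sigma_P_median: float = 0.9
    sigma_P_logsd: float = 0.15
    whf_sd: float = 0.05
    alphas: TransformCoefficients = field(
        default_factory=lambda: TransformCoefficients(0.04, 0.045, 0.14, 0.05))

    def __post_init__(self) -> None:
        for name in ("c_Q_logsd", "c_E_logsd", "c_P_logsd", "c_S_logsd",
                     "theta_P_sd", "sigma_P_logsd", "whf_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Full generator configuration; defaults give a plausible school cohort."""

    n_per_sex: int = 100
    seed: int = 0
    female: SexParams = field(default_factory=lambda: SexParams(
        c_Q_median=98.0, c_E_median=52.0, c_P_median=17.0, c_S_median=0.003,
        theta_P_mean=11.0,
        alphas=TransformCoefficients(0.0409, 0.0450, 0.0824, 0.05)))
    male: SexParams = field(default_factory=lambda: SexParams(
        c_Q_median=103.0, c_E_median=55.0, c_P_median=22.0, c_S_median=0.003,
        theta_P_mean=13.0,
        alphas=TransformCoefficients(0.0459, 0.0410, 0.0682, 0.05)))
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    visit_jitter_sd: float = 0.05
    height_noise_sd: float = 0.5   # cm
    weight_noise_sd: float = 0.05  # kg^0.5
    contamination_fraction: float = 0.0  # extreme-BMI subjects (WHF outliers)
    shape: dict[str, ShapeConstants] = field(
        default_factory=lambda: dict(DEFAULT_SHAPE))

    def __post_init__(self) -> None:
        if self.n_per_sex < 1:
            raise ValidationError("n_per_sex must be >= 1")
        for name in ("visit_jitter_sd", "height_noise_sd", "weight_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 <= self.contamination_fraction < 1.0):
            raise ValidationError("contamination_fraction must be in [0, 1)")

    def sex_params(self, sex: str) -> SexParams:
        return self.female if sex == "F" else self.male


def default_config(**overrides) -> CohortConfig:
    """The default cohort configuration, with keyword overrides."""
    return replace(CohortConfig(), **overrides) if overrides else CohortConfig()


@dataclass(frozen=True)
class EffectSpec:
    """A planted subgroup effect for :func:`make_subgroup_cohort`.

    ``theta_shift`` moves the pubertal-timing mean (years);
    ``theta_margin_sd`` adds a half-normal margin in the shift direction so
    planted members land beyond a classification band edge rather than on it.
    ``height_scale`` multiplies the basic scales c_Q and c_E (taller/shorter
    at onset); ``c_P_scale`` multiplies the pubertal scale; ``whf_shift``
    moves the constitutional factor.
    """

    name: str
    fraction: float
    theta_shift: float = 0.0
    theta_margin_sd: float = 0.0
    theta_sd_override: float | None = None
    height_scale: float = 1.0
    c_P_scale: float = 1.0
    whf_shift: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValidationError("fraction must be in (0, 1]")


_SEX_CODE = {"F": 0, "M": 1}


def _subject_rng(seed: int, sex: str, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, _SEX_CODE[sex], index])


def draw_individual(config: CohortConfig, sex: str, index: int,
                    effect: EffectSpec | None = None
                    ) -> tuple[QEPSParams, float]:
    """Draw one subject's true height parameters and WHF (reproducible)."""
    sp = config.sex_params(sex)
    rng = _subject_rng(config.seed, sex, index)
    c_Q = sp.c_Q_median * np.exp(rng.normal(0, sp.c_Q_logsd))
    c_E = sp.c_E_median * np.exp(rng.normal(0, sp.c_E_logsd))
    c_P = sp.c_P_median * np.exp(rng.normal(0, sp.c_P_logsd))
    c_S = sp.c_S_median * np.exp(rng.normal(0, sp.c_S_logsd))
    theta_sd = sp.theta_P_sd
    theta_mean = sp.theta_P_mean
    if effect is not None:
        if effect.theta_sd_override is not None:
            theta_sd = effect.theta_sd_override
        theta_mean = theta_mean + effect.theta_shift
    theta = rng.normal(theta_mean, theta_sd)
    if effect is not None and effect.theta_margin_sd > 0 and effect.theta_shift:
        theta += np.sign(effect.theta_shift) * abs(
            rng.normal(0, effect.theta_margin_sd))
    sigma = sp.sigma_P_median * np.exp(rng.normal(0, sp.sigma_P_logsd))
    whf = rng.normal(0.0, sp.whf_sd)
    if effect is not None:
        c_Q *= effect.height_scale
        c_E *= effect.height_scale
        c_P *= effect.c_P_scale
        whf += effect.whf_shift
    params = QEPSParams(c_Q=c_Q, c_E=c_E, c_P=c_P, c_S=c_S,
                        theta_P=float(theta), sigma_P=float(sigma),
                        trait="height")
    return params, float(whf)


def _visit_ages(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    ages = np.asarray(config.schedule, dtype=float) + rng.normal(
        0.0, config.visit_jitter_sd, size=len(config.schedule))
    ages = np.sort(np.clip(ages, 0.05, None))
    # keep visit ages strictly increasing after jitter
    for k in range(1, ages.size):
        if ages[k] <= ages[k - 1]:
            ages[k] = ages[k - 1] + 1e-3
    return np.round(ages, 3)


def _simulate_subject(config: CohortConfig, sex: str, index: int,
                      effect: EffectSpec | None
                      ) -> tuple[pd.DataFrame, dict]:
    params, whf = draw_individual(config, sex, index, effect)
    sp = config.sex_params(sex)
    shape = config.shape[sex]
    # separate stream from the parameter draws so each stays reproducible
    rng = np.random.default_rng([config.seed, _SEX_CODE[sex], index, 1])

    contaminated = False
    if config.contamination_fraction > 0:
        if rng.uniform() < config.contamination_fraction:
            contaminated = True
            whf += float(rng.choice([-0.25, 0.35]))

    ages = _visit_ages(config, rng)
    true_height = eval_components(params, shape, ages).total
    heights = true_height + rng.normal(0, config.height_noise_sd, ages.size)

    wparams = predict_weight(params, sp.alphas)
    sqrtw_true = (1.0 + whf) * eval_components(wparams, shape, ages).total
    sqrtw_obs = sqrtw_true + rng.normal(0, config.weight_noise_sd, ages.size)
    sqrtw_obs = np.clip(sqrtw_obs, 1.05, None)  # keep weights physical
    weights = sqrtw_obs**2

    sid = f"{sex}{index:04d}"
    frame = pd.DataFrame({
        "subject_id": sid, "sex": sex, "age_years": ages,
        "height_cm": np.round(heights, 2), "weight_kg": np.round(weights, 3),
    })
    truth = {
        "subject_id": sid, "sex": sex,
        "c_Q": params.c_Q, "c_E": params.c_E, "c_P": params.c_P,
        "c_S": params.c_S, "theta_P": params.theta_P,
        "sigma_P": params.sigma_P, "whf": whf,
        "age_p5": age_p5(params),
        "tphv": age_at_peak_velocity(params, shape),
        "adult_height": float(eval_components(params, shape, [40.0]).total[0]),
        "monotone_pre_noise": bool(np.all(np.diff(true_height) >= -1e-9)),
        "contaminated": contaminated,
        "group": effect.name if effect is not None else "control",
    }
    return frame, truth


def simulate_cohort(config: CohortConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-sex longitudinal cohort.

    Returns the long-format cohort table (one row per visit) and the truth
    table (one row per subject with the generating parameters and landmarks).
    Deterministic given ``config.seed``.
    """
    config = config or CohortConfig()
    frames, truths = [], []
    for sex in ("F", "M"):
        for i in range(config.n_per_sex):
            frame, truth = _simulate_subject(config, sex, i, None)
            frames.append(frame)
            truths.append(truth)
    return (pd.concat(frames, ignore_index=True),
            pd.DataFrame(truths))


def make_subgroup_cohort(config: CohortConfig,
                         effects: Sequence[EffectSpec],
                         sexes: Sequence[str] = ("F", "M")
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort with planted subgroup effects.

    Subjects are assigned to effect groups in contiguous index blocks per
    sex, sized by each effect's ``fraction``; the remainder is the unshifted
    ``control`` group.  The truth table carries the group assignment.
    """
    total_frac = sum(e.fraction for e in effects)
    if total_frac > 1.0 + 1e-9:
        raise ValidationError("effect fractions sum to more than 1")
    frames, truths = [], []
    for sex in sexes:
        n = config.n_per_sex
        bounds = []
        start = 0
        for e in effects:
            size = int(round(e.fraction * n))
            bounds.append((start, start + size, e))
            start += size
        for i in range(n):
            effect = None
            for lo, hi, e in bounds:
                if lo <= i < hi:
                    effect = e
                    break
            frame, truth = _simulate_subject(config, sex, i, effect)
            frames.append(frame)
            truths.append(truth)
    return (pd.concat(frames, ignore_index=True), pd.DataFrame(truths))
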