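"""End-to-end orchestration: cohort table in, fitted curves and tables out.

The canonical run is: fit each subject's height series, estimate the per-sex
height-to-weight transform from the pooled weight observations, predict each
subject's sqrt-weight curve, fit the individual weight-height factor, and
collect :class:`~qepsgrowth.reference.IndividualCurve` objects ready for
reference construction.  Subjects whose series cannot support a fit are
reported, not silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .fitting import (
    FitOptions,
    FitResult,
    InsufficientCoverageError,
    TransformCoefficients,
    WHFResult,
    estimate_transform,
    fit_height,
    fit_whf,
    predict_weight,
)
from .io_utils import measurements_by_subject
from .qeps_model import DEFAULT_SHAPE, ShapeConstants, age_p5
from .reference import IndividualCurve

__all__ = ["PipelineResult", "run_pipeline", "fit_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Fits, transforms and curves for one cohort."""

    height_fits: dict[str, FitResult]
    sex_of: dict[str, str]
    transforms: dict[str, TransformCoefficients]
    whf: dict[str, WHFResult]
    skipped: dict[str, str] = field(default_factory=dict)

    def curves(self, trait: str = "weight",
               shapes: dict[str, ShapeConstants] | None = None,
               sex: str | None = None) -> list[IndividualCurve]:
        """Individual fitted curves (weight incl. WHF), alignment-ready."""
        shapes = shapes or DEFAULT_SHAPE
        out = []
        for sid, fit in self.height_fits.items():
            s = self.sex_of[sid]
            if sex is not None and s != sex:
                continue
            hp = fit.params
            onset = age_p5(hp)
            if trait == "height":
                out.append(IndividualCurve(subject_id=sid, params=hp,
                                           shape=shapes[s], age_p5=onset))
            else:
                wp = predict_weight(hp, self.transforms[s])
                out.append(IndividualCurve(
                    subject_id=sid, params=wp, shape=shapes[s],
                    whf=self.whf[sid].whf, age_p5=onset))
        return out

    def params_frame(self) -> pd.DataFrame:
        """Per-subject height parameters and WHF as a flat table."""
        rows = []
        for sid, fit in self.height_fits.items():
            p = fit.params
            rows.append({
                "subject_id": sid, "sex": self.sex_of[sid], "trait": p.trait,
                "c_Q": p.c_Q, "c_E": p.c_E, "c_P": p.c_P, "c_S": p.c_S,
                "theta_P": p.theta_P, "sigma_P": p.sigma_P,
                "whf": self.whf[sid].whf if sid in self.whf else float("nan"),
                "rmse": fit.rmse, "n_points": fit.n_points,
                "converged": fit.converged,
            })
        return pd.DataFrame(rows)


def fit_cohort(cohort: pd.DataFrame,
               shapes: dict[str, ShapeConstants] | None = None,
               options: FitOptions | None = None
               ) -> tuple[dict[str, FitResult], dict[str, str], dict[str, str]]:
    """Fit height curves for every subject in a cohort table.

    Returns (fits, sex_of, skipped) where ``skipped`` maps subject ids to the
    reason their series could not be fitted.
    """
    shapes = shapes or DEFAULT_SHAPE
    by_subject = measurements_by_subject(cohort)
    fits: dict[str, FitResult] = {}
    sex_of: dict[str, str] = {}
    skipped: dict[str, str] = {}
    for sid, ms in by_subject.items():
        sex = ms[0].sex
        try:
            fits[sid] = fit_height(ms, shapes[sex], options)
            sex_of[sid] = sex
        except InsufficientCoverageError as err:
            skipped[sid] = str(err)
            logger.warning("skipping %s: %s", sid, err)
    return fits, sex_of, skipped


def run_pipeline(cohort: pd.DataFrame,
                 shapes: dict[str, ShapeConstants] | None = None,
                 options: FitOptions | None = None,
                 min_transform_subjects: int = 30) -> PipelineResult:
    """Run fit -> transform -> WHF on a cohort table."""
    shapes = shapes or DEFAULT_SHAPE
    by_subject = measurements_by_subject(cohort)
    fits, sex_of, skipped = fit_cohort(cohort, shapes, options)

    transforms: dict[str, TransformCoefficients] = {}
    for sex in sorted(set(sex_of.values())):
        pairs = []
        for sid, fit in fits.items():
            if sex_of[sid] != sex:
                continue
            wobs = [(m.age, m.weight) for m in by_subject[sid]
                    if m.weight is not None]
            pairs.append((fit.params, wobs))
        transforms[sex] = estimate_transform(
            pairs, shapes[sex], min_subjects=min_transform_subjects)
        logger.info("transform %s: %s", sex, transforms[sex])

    whf: dict[str, WHFResult] = {}
    for sid, fit in list(fits.items()):
        wobs = [(m.age, m.weight) for m in by_subject[sid]
                if m.weight is not None]
        wp = predict_weight(fit.params, transforms[sex_of[sid]])
        try:
            whf[sid] = fit_whf(wobs, wp, shapes[sex_of[sid]])
        except InsufficientCoverageError as err:
            skipped[sid] = str(err)
            del fits[sid], sex_of[sid]
    return PipelineResult(height_fits=fits, sex_of=sex_of,
                          transforms=transforms, whf=whf, skipped=skipped)
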