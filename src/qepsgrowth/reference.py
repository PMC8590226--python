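"""Growth references on chronological and puberty-aligned age axes.

A reference is built from *fitted* individual curves, not raw observations:
per grid point the median and standard deviation of the curve values across
subjects are taken, in kg^0.5 for weight (the scale on which the components
are additive and residuals close to symmetric) or cm for height.  SDS bands
follow as ``median ± k * SD``.

The puberty-aligned axis re-indexes every curve by ``t' = t - AgeP5``, where
AgeP5 is the age at which 5% of the *height* P-function gain was attained —
the operational onset of the pubertal growth spurt.  Weight curves are
aligned by the height-derived AgeP5 as well, so that both traits share one
biological clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .qeps_model import (
    QEPSParams,
    ShapeConstants,
    ValidationError,
    age_p5,
    eval_components,
)

__all__ = [
    "COMPONENTS",
    "CHRONOLOGICAL_GRID",
    "ALIGNED_GRID",
    "IndividualCurve",
    "AlignedCurve",
    "ReferenceTable",
    "OutOfReferenceRangeError",
    "UnalignableSubjectError",
    "align_curve",
    "build_reference",
    "sds",
    "value_at_sds",
    "assess_individual",
]

COMPONENTS = ("total", "basic", "p_specific")

#: Default chronological grid, 4-20 years in 0.1-y steps.
CHRONOLOGICAL_GRID = np.round(np.arange(40, 201) * 0.1, 10)
#: Default puberty-aligned grid, -4 to +10 years around spurt onset.
ALIGNED_GRID = np.round(np.arange(-40, 101) * 0.1, 10)


class OutOfReferenceRangeError(ValueError):
    """Query age falls outside the reference grid."""


class UnalignableSubjectError(ValueError):
    """Subject has no pubertal component, hence no spurt onset to align to."""


@dataclass(frozen=True)
class IndividualCurve:
    """A fitted individual curve ready for reference construction.

    ``whf`` scales the whole sqrt-weight curve by ``(1 + whf)`` and is 0 for
    height.  ``age_p5`` is the height-derived spurt onset used for alignment.
    """

    subject_id: str
    params: QEPSParams
    shape: ShapeConstants
    whf: float = 0.0
    age_p5: float | None = None

    def component_values(self, ages: np.ndarray) -> dict[str, np.ndarray]:
        comp = eval_components(self.params, self.shape, ages)
        k = 1.0 + self.whf
        return {"total": k * comp.total, "basic": k * comp.basic,
                "p_specific": k * comp.P}

    def onset(self) -> float:
        if self.age_p5 is not None:
            return self.age_p5
        if self.params.c_P <= 0:
            raise UnalignableSubjectError(
                f"subject {self.subject_id}: no pubertal component to align"
            )
        return age_p5(self.params)


@dataclass(frozen=True)
class AlignedCurve:
    """One subject's component curves on the puberty-age grid t' = t - AgeP5."""

    subject_id: str
    age_p5: float
    grid: np.ndarray
    values: Mapping[str, np.ndarray]


@dataclass(frozen=True)
class ReferenceTable:
    """Per-sex reference: median and SD per grid point and component.

    ``axis`` is ``"chronological"`` (grid in years of age) or
    ``"puberty_aligned"`` (grid in years since spurt onset).  Values are in
    kg^0.5 for weight and cm for height.
    """

    sex: str
    axis: str
    trait: str
    grid: np.ndarray
    median: Mapping[str, np.ndarray]
    sd: Mapping[str, np.ndarray]
    n_subjects: int

    def __post_init__(self) -> None:
        if self.axis not in ("chronological", "puberty_aligned"):
            raise ValidationError(f"unknown axis {self.axis!r}")
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 1 or g.size < 2 or np.any(np.diff(g) <= 0):
            raise ValidationError("grid must be strictly increasing")
        for comp in COMPONENTS:
            if comp not in self.median or comp not in self.sd:
                raise ValidationError(f"missing component {comp!r}")
            if np.any(np.asarray(self.sd[comp]) <= 0):
                raise ValidationError(
                    f"SD must be positive everywhere (component {comp!r}); "
                    "degenerate population"
                )

    def _interp(self, table: Mapping[str, np.ndarray], age: float,
                component: str) -> float:
        g = np.asarray(self.grid, dtype=float)
        if age < g[0] - 1e-9 or age > g[-1] + 1e-9:
            raise OutOfReferenceRangeError(
                f"age {age:.2f} outside reference range [{g[0]:.1f}, {g[-1]:.1f}]"
            )
        return float(np.interp(age, g, np.asarray(table[component], dtype=float)))

    def median_at(self, age: float, component: str = "total") -> float:
        return self._interp(self.median, age, component)

    def sd_at(self, age: float, component: str = "total") -> float:
        return self._interp(self.sd, age, component)


def align_curve(curve: IndividualCurve, height_age_p5: float | None = None,
                grid: np.ndarray = ALIGNED_GRID) -> AlignedCurve:
    """Evaluate a subject's components on the puberty-aligned grid.

    The value at pubertal age ``t'`` is the component at chronological age
    ``AgeP5 + t'``.  Alignment always uses the height-derived AgeP5, also for
    weight curves.
    """
    onset = height_age_p5 if height_age_p5 is not None else curve.onset()
    if not np.isfinite(onset):
        raise UnalignableSubjectError(
            f"subject {curve.subject_id}: non-finite onset age"
        )
    grid = np.asarray(grid, dtype=float)
    return AlignedCurve(subject_id=curve.subject_id, age_p5=float(onset),
                        grid=grid,
                        values=curve.component_values(onset + grid))


def build_reference(curves: Sequence[IndividualCurve], axis: str,
                    grid: np.ndarray | None = None,
                    sex: str = "F") -> ReferenceTable:
    """Build a reference table from fitted individual curves.

    Per grid point the cross-subject median and (ddof = 1) standard deviation
    of the fitted curve values are computed for the total, basic and
    puberty-specific components.  Using fitted curves rather than raw visits
    removes measurement error from the reference spread.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValidationError("need at least 2 subjects to build a reference")
    if grid is None:
        grid = CHRONOLOGICAL_GRID if axis == "chronological" else ALIGNED_GRID
    grid = np.asarray(grid, dtype=float)
    traits = {c.params.trait for c in curves}
    if len(traits) != 1:
        raise ValidationError("curves mix traits")
    stacks: dict[str, list[np.ndarray]] = {c: [] for c in COMPONENTS}
    for curve in curves:
        if axis == "puberty_aligned":
            vals = align_curve(curve, grid=grid).values
        else:
            vals = curve.component_values(grid)
        for comp in COMPONENTS:
            stacks[comp].append(vals[comp])
    median = {c: np.median(np.vstack(v), axis=0) for c, v in stacks.items()}
    sd = {c: np.std(np.vstack(v), axis=0, ddof=1) for c, v in stacks.items()}
    return ReferenceTable(sex=sex, axis=axis, trait=traits.pop(), grid=grid,
                          median=median, sd=sd, n_subjects=len(curves))


def sds(value: float, age: float, table: ReferenceTable,
        component: str = "total") -> float:
    """Standard deviation score of an observed value against a reference.

    ``value`` is in natural units (kg for weight, cm for height); the score
    is computed on the reference scale (kg^0.5 for weight) as
    ``(x - median) / SD`` with linear interpolation between grid points.
    """
    if value < 0:
        raise ValidationError("value must be non-negative")
    x = np.sqrt(value) if table.trait == "weight" else float(value)
    m = table.median_at(age, component)
    s = table.sd_at(age, component)
    return (x - m) / s


def value_at_sds(z: float, age: float, table: ReferenceTable,
                 component: str = "total") -> float:
    """Inverse of :func:`sds`: the natural-unit value at a given score.

    Raises :class:`ValidationError` when the score implies a negative value
    on the reference scale (possible for low scores of components whose
    median is near zero), since no kg or cm observation maps there.
    """
    x = table.median_at(age, component) + z * table.sd_at(age, component)
    if x < 0:
        raise ValidationError(
            f"SDS {z:.2f} implies a negative {table.trait} value at this age"
        )
    return float(x * x) if table.trait == "weight" else float(x)


def assess_individual(
    measurements: Iterable, onset_age: float,
    height_table: ReferenceTable | None,
    weight_table: ReferenceTable | None,
) -> pd.DataFrame:
    """Score one child's visits against puberty-aligned references.

    Used prospectively: ``onset_age`` is supplied externally (secondary sex
    characteristics, or height take-off against a prepubertal reference).
    Every visit at chronological age ``a`` is re-expressed at pubertal age
    ``t' = a - onset_age`` and scored against the aligned total-component
    tables; visits whose ``t'`` falls outside the reference span are returned
    unscored (``scored`` False, SDS NaN) rather than extrapolated.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValidationError("no measurements to assess")
    for tbl, trait in ((height_table, "height"), (weight_table, "weight")):
        if tbl is not None and (tbl.axis != "puberty_aligned" or tbl.trait != trait):
            raise ValidationError(f"need a puberty-aligned {trait} table")
    rows = []
    for m in measurements:
        t_pub = m.age - onset_age
        h_sds = w_sds = np.nan
        scored = False
        for tbl, obs in ((height_table, m.height), (weight_table, m.weight)):
            if tbl is None or obs is None:
                continue
            try:
                z = sds(obs, t_pub, tbl, "total")
            except OutOfReferenceRangeError:
                continue
            scored = True
            if tbl.trait == "height":
                h_sds = z
            else:
                w_sds = z
        rows.append({"subject_id": m.subject_id, "age": m.age,
                     "pubertal_age": t_pub, "height_sds": h_sds,
                     "weight_sds": w_sds, "scored": scored})
    return pd.DataFrame(rows)
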