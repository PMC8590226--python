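"""Cohort-assembly filters and an empirical BMI SDS reference.

Reference populations for weight must not be dominated by unhealthy weight
development, so subjects with extreme BMI at any visit are excluded before
modelling.  The thresholds are configuration, not constants: the default is
±3 SDS against an empirical, cohort-derived BMI reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionConfig",
    "BmiReference",
    "build_bmi_reference",
    "bmi_sds",
    "exclude_extreme_bmi",
]


@dataclass(frozen=True)
class ExclusionConfig:
    """BMI SDS bounds outside which a subject is excluded (any visit)."""

    bmi_sds_upper: float = 3.0
    bmi_sds_lower: float = -3.0

    def __post_init__(self) -> None:
        if not (self.bmi_sds_upper > self.bmi_sds_lower):
            raise ValueError("upper bound must exceed lower bound")


@dataclass(frozen=True)
class BmiReference:
    """Per-sex age grid of median and SD of BMI (kg/m^2), binned empirically."""

    ages: Mapping[str, np.ndarray]
    median: Mapping[str, np.ndarray]
    sd: Mapping[str, np.ndarray]


def _bmi(df: pd.DataFrame) -> pd.Series:
    return df["weight_kg"] / (df["height_cm"] / 100.0) ** 2


def build_bmi_reference(cohort: pd.DataFrame, bin_width: float = 1.0,
                        min_per_bin: int = 5) -> BmiReference:
    """Empirical BMI reference from a cohort table.

    Visits with both height and weight are pooled per sex into age bins of
    ``bin_width`` years; bins with fewer than ``min_per_bin`` visits are
    dropped.  Queries interpolate linearly between bin centres and clamp at
    the ends.
    """
    ages: dict[str, np.ndarray] = {}
    median: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    obs = cohort.dropna(subset=["height_cm", "weight_kg"]).copy()
    obs["bmi"] = _bmi(obs)
    for sex, grp in obs.groupby("sex"):
        centre = (np.floor(grp["age_years"] / bin_width) + 0.5) * bin_width
        stats = grp.assign(centre=centre).groupby("centre")["bmi"].agg(
            ["median", "std", "count"])
        stats = stats[(stats["count"] >= min_per_bin) & (stats["std"] > 0)]
        if stats.empty:
            raise ValueError(f"not enough data to build a BMI reference for {sex}")
        ages[sex] = stats.index.to_numpy(dtype=float)
        median[sex] = stats["median"].to_numpy(dtype=float)
        sd[sex] = stats["std"].to_numpy(dtype=float)
    return BmiReference(ages=ages, median=median, sd=sd)


def bmi_sds(bmi: float, age: float, sex: str, ref: BmiReference) -> float:
    """BMI SDS against the empirical reference (clamped extrapolation)."""
    m = float(np.interp(age, ref.ages[sex], ref.median[sex]))
    s = float(np.interp(age, ref.ages[sex], ref.sd[sex]))
    return (bmi - m) / s


def exclude_extreme_bmi(
    cohort: pd.DataFrame,
    config: ExclusionConfig | None = None,
    reference: BmiReference | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a cohort into retained subjects and an exclusion report.

    A subject is excluded when *any* visit's BMI SDS falls outside the
    configured bounds.  The report lists one row per triggering visit
    (subject_id, age_years, bmi, bmi_sds).  Retained plus excluded subjects
    partition the input, and the operation is idempotent.
    """
    config = config or ExclusionConfig()
    if cohort.empty:
        return cohort.copy(), pd.DataFrame(
            columns=["subject_id", "age_years", "bmi", "bmi_sds"])
    if reference is None:
        reference = build_bmi_reference(cohort)
    obs = cohort.dropna(subset=["height_cm", "weight_kg"]).copy()
    obs["bmi"] = _bmi(obs)
    obs["bmi_sds"] = [
        bmi_sds(b, a, s, reference)
        for b, a, s in zip(obs["bmi"], obs["age_years"], obs["sex"])
    ]
    flagged = obs[(obs["bmi_sds"] > config.bmi_sds_upper)
                  | (obs["bmi_sds"] < config.bmi_sds_lower)]
    report = flagged[["subject_id", "age_years", "bmi", "bmi_sds"]].reset_index(
        drop=True)
    excluded_ids = set(report["subject_id"])
    retained = cohort[~cohort["subject_id"].isin(excluded_ids)].reset_index(
        drop=True)
    return retained, report
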