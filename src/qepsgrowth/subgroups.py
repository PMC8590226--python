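"""Prepubertal-characteristic subgroups and group-mean SDS trajectories.

Subjects are classified on three independent dimensions measured before or
at the onset of puberty: pubertal timing (deviation of the age at peak
height velocity from the sex-specific cohort mean), stature at spurt onset,
and highest childhood BMI.  Band edges are strict inequalities; subjects in
the gaps stay unlabelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .filters import BmiReference, bmi_sds

__all__ = [
    "SubgroupLabel",
    "BMI_WINDOW",
    "timing_label",
    "stature_label",
    "childhood_bmi_label",
    "group_mean_sds",
]

#: Childhood window (years) for the peak-BMI classification, per sex.
BMI_WINDOW = {"F": (3.5, 7.0), "M": (3.5, 8.0)}

TIMING_EARLY = -1.5   # years before cohort-mean TPHV
TIMING_LATE = 1.5     # years after
TIMING_AVERAGE = 0.25  # half-width of the average band
STATURE_CUT = 1.5     # |SDS| threshold for tall/short
BMI_CUT = 1.5         # |SDS| threshold for high/low childhood BMI


@dataclass(frozen=True)
class SubgroupLabel:
    dimension: str  # timing | stature | childhood_bmi
    label: str


def timing_label(tphv: float, population_mean_tphv: float) -> SubgroupLabel:
    """Early / average / late maturation by TPHV deviation from cohort mean.

    Early is more than 1.5 y before the mean, late more than 1.5 y after,
    average within ±0.25 y; the gaps in between are unlabelled.
    """
    d = tphv - population_mean_tphv
    if d < TIMING_EARLY:
        label = "early"
    elif abs(d) <= TIMING_AVERAGE:
        label = "average"
    elif d > TIMING_LATE:
        label = "late"
    else:
        label = "unlabelled"
    return SubgroupLabel(dimension="timing", label=label)


def stature_label(height_sds_at_onset: float) -> SubgroupLabel:
    """Tall (> +1.5 SDS) or short (< -1.5 SDS) stature at spurt onset."""
    if height_sds_at_onset > STATURE_CUT:
        label = "tall"
    elif height_sds_at_onset < -STATURE_CUT:
        label = "short"
    else:
        label = "unlabelled"
    return SubgroupLabel(dimension="stature", label=label)


def childhood_bmi_label(measurements: Iterable, bmi_reference: BmiReference,
                        sex: str) -> SubgroupLabel:
    """High/low childhood BMI by the peak BMI SDS inside the sex window.

    The window is 3.5-7 y for girls and 3.5-8 y for boys; visits need both
    height and weight.  No visit in the window leaves the subject unlabelled
    with a warning.
    """
    lo, hi = BMI_WINDOW[sex]
    scores = []
    for m in measurements:
        if m.height is None or m.weight is None:
            continue
        if not (lo <= m.age <= hi):
            continue
        bmi = m.weight / (m.height / 100.0) ** 2
        scores.append(bmi_sds(bmi, m.age, sex, bmi_reference))
    if not scores:
        warnings.warn("no visits inside the childhood BMI window; unlabelled",
                      stacklevel=2)
        return SubgroupLabel(dimension="childhood_bmi", label="unlabelled")
    peak = max(scores)
    if peak > BMI_CUT:
        label = "high_bmi"
    elif peak < -BMI_CUT:
        label = "low_bmi"
    else:
        label = "unlabelled"
    return SubgroupLabel(dimension="childhood_bmi", label=label)


def group_mean_sds(trajectories: Mapping[str, np.ndarray],
                   labels: Mapping[str, str],
                   grid: np.ndarray) -> pd.DataFrame:
    """Group-mean SDS trajectory with a 95% CI per grid point.

    ``trajectories`` maps subject id to an SDS array on ``grid``; ``labels``
    maps subject id to a group label.  The CI is the normal approximation
    ``mean ± 1.96 SD / sqrt(n)``.  Groups with fewer than two members are
    dropped with a warning.
    """
    grid = np.asarray(grid, dtype=float)
    by_group: dict[str, list[np.ndarray]] = {}
    for sid, traj in trajectories.items():
        lab = labels.get(sid, "unlabelled")
        traj = np.asarray(traj, dtype=float)
        if traj.shape != grid.shape:
            raise ValueError(f"trajectory for {sid} does not match grid")
        by_group.setdefault(lab, []).append(traj)
    frames = []
    for lab, rows in sorted(by_group.items()):
        n = len(rows)
        if n < 2:
            warnings.warn(f"group {lab!r} has n={n} < 2; dropped", stacklevel=2)
            continue
        arr = np.vstack(rows)
        mean = arr.mean(axis=0)
        half = 1.96 * arr.std(axis=0, ddof=1) / np.sqrt(n)
        frames.append(pd.DataFrame({
            "group": lab, "grid_age": grid, "mean_sds": mean,
            "ci_low": mean - half, "ci_high": mean + half, "n": n,
        }))
    if not frames:
        return pd.DataFrame(columns=["group", "grid_age", "mean_sds",
                                     "ci_low", "ci_high", "n"])
    return pd.concat(frames, ignore_index=True)
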