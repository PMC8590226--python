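"""File formats and configuration.

Everything on disk is plain CSV (UTF-8, comma separated, "." decimal point)
or YAML: the long-format cohort table, per-subject parameter tables,
reference tables, and the configuration file.  Sex is encoded F/M in files;
reference CSVs carry their metadata (sex, axis, trait) in a comment header
so they round-trip.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitOptions, Measurement, TransformCoefficients
from .filters import ExclusionConfig
from .qeps_model import QEPSParams, ShapeConstants
from .reference import COMPONENTS, ReferenceTable
from .synthetic_cohort import CohortConfig, SexParams

__all__ = [
    "SchemaError",
    "AppConfig",
    "read_cohort",
    "write_cohort",
    "measurements_by_subject",
    "write_params",
    "read_params",
    "write_reference",
    "read_reference",
    "load_config",
    "dump_config",
    "config_hash",
]

COHORT_COLUMNS = ("subject_id", "sex", "age_years", "height_cm", "weight_kg")
REQUIRED_COLUMNS = ("subject_id", "sex", "age_years")
PARAM_COLUMNS = ("subject_id", "sex", "trait", "c_Q", "c_E", "c_P", "c_S",
                 "theta_P", "sigma_P", "whf", "rmse", "n_points", "converged")


class SchemaError(ValueError):
    """A file does not match the expected schema."""


# --- cohort tables -----------------------------------------------------------


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    Raises :class:`SchemaError` naming missing columns, non-numeric fields
    (with 1-based data line numbers) or duplicate (subject, age) rows.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in ("height_cm", "weight_kg"):
        if col not in df.columns:
            df[col] = np.nan
    out = df[list(COHORT_COLUMNS)].copy()
    for col in ("age_years", "height_cm", "weight_kg"):
        num = pd.to_numeric(out[col], errors="coerce")
        bad = num.isna() & out[col].notna() & (out[col].astype(str).str.strip() != "")
        if bad.any():
            lines = ", ".join(str(i + 2) for i in out.index[bad][:10])
            raise SchemaError(f"non-numeric {col} at file line(s) {lines}")
        out[col] = num
    if out["age_years"].isna().any():
        lines = ", ".join(
            str(i + 2) for i in out.index[out["age_years"].isna()][:10])
        raise SchemaError(f"missing age_years at file line(s) {lines}")
    if (out["age_years"] < 0).any():
        raise SchemaError("age_years must be non-negative")
    bad_sex = ~out["sex"].isin(["F", "M"])
    if bad_sex.any():
        lines = ", ".join(str(i + 2) for i in out.index[bad_sex][:10])
        raise SchemaError(f"sex must be F or M at file line(s) {lines}")
    dup = out.duplicated(subset=["subject_id", "age_years"], keep=False)
    if dup.any():
        lines = ", ".join(str(i + 2) for i in out.index[dup][:10])
        raise SchemaError(f"duplicate (subject_id, age_years) rows at "
                          f"file line(s) {lines}")
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def measurements_by_subject(cohort: pd.DataFrame) -> dict[str, list[Measurement]]:
    """Convert a cohort table to per-subject Measurement lists."""
    out: dict[str, list[Measurement]] = {}
    for row in cohort.itertuples(index=False):
        h = None if pd.isna(row.height_cm) else float(row.height_cm)
        w = None if pd.isna(row.weight_kg) else float(row.weight_kg)
        out.setdefault(str(row.subject_id), []).append(Measurement(
            subject_id=str(row.subject_id), sex=str(row.sex),
            age=float(row.age_years), height=h, weight=w))
    return out


# --- parameter tables --------------------------------------------------------


def write_params(rows: pd.DataFrame, path) -> None:
    missing = [c for c in PARAM_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(f"missing parameter column(s): {', '.join(missing)}")
    rows.to_csv(path, index=False, columns=list(PARAM_COLUMNS))


def read_params(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing parameter column(s): {', '.join(missing)}")
    return df


def params_from_row(row) -> QEPSParams:
    return QEPSParams(c_Q=float(row.c_Q), c_E=float(row.c_E),
                      c_P=float(row.c_P), c_S=float(row.c_S),
                      theta_P=float(row.theta_P), sigma_P=float(row.sigma_P),
                      trait=str(row.trait))


# --- reference tables --------------------------------------------------------


def write_reference(table: ReferenceTable, path) -> None:
    """Write a reference table as CSV, one row per (grid point, component).

    Weight tables carry median/SD in kg^0.5 plus a derived median_kg column
    (display only, never read back); height tables use cm.
    """
    rows = []
    for comp in COMPONENTS:
        med = np.asarray(table.median[comp], dtype=float)
        sd = np.asarray(table.sd[comp], dtype=float)
        for g, m, s in zip(table.grid, med, sd):
            rows.append((float(g), comp, m, s))
    if table.trait == "weight":
        df = pd.DataFrame(rows, columns=["axis_age", "component",
                                         "median_sqrtkg", "sd_sqrtkg"])
        df["median_kg"] = df["median_sqrtkg"] ** 2
    else:
        df = pd.DataFrame(rows, columns=["axis_age", "component",
                                         "median_cm", "sd_cm"])
    df["n"] = table.n_subjects
    buf = io.StringIO()
    buf.write(f"# qepsgrowth-reference sex={table.sex} axis={table.axis} "
              f"trait={table.trait}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_reference(path) -> ReferenceTable:
    text = Path(path).read_text(encoding="utf-8")
    header, _, body = text.partition("\n")
    if not header.startswith("# qepsgrowth-reference"):
        raise SchemaError("not a reference CSV (missing metadata header)")
    meta = dict(kv.split("=", 1) for kv in header.split()[2:])
    df = pd.read_csv(io.StringIO(body))
    med_col = "median_sqrtkg" if meta["trait"] == "weight" else "median_cm"
    sd_col = "sd_sqrtkg" if meta["trait"] == "weight" else "sd_cm"
    grid = np.array(sorted(df["axis_age"].unique()), dtype=float)
    median, sd = {}, {}
    for comp in COMPONENTS:
        sub = df[df["component"] == comp].sort_values("axis_age")
        if sub.shape[0] != grid.size:
            raise SchemaError(f"component {comp!r} missing or incomplete")
        median[comp] = sub[med_col].to_numpy(dtype=float)
        sd[comp] = sub[sd_col].to_numpy(dtype=float)
    return ReferenceTable(sex=meta["sex"], axis=meta["axis"],
                          trait=meta["trait"], grid=grid, median=median,
                          sd=sd, n_subjects=int(df["n"].iloc[0]))


# --- configuration -----------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class AppConfig:
    """Top-level tool configuration: cohort generator, fitter, exclusions."""

    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    fit: FitOptions = dataclasses.field(default_factory=FitOptions)
    exclusion: ExclusionConfig = dataclasses.field(
        default_factory=ExclusionConfig)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def dump_config(config: AppConfig | None = None) -> str:
    """Serialize a configuration (defaults when omitted) to YAML."""
    config = config or AppConfig()
    return yaml.safe_dump(_to_plain(config), sort_keys=True)


def _sex_params_from_dict(d: dict) -> SexParams:
    d = dict(d)
    alphas = d.pop("alphas")
    return SexParams(alphas=TransformCoefficients(**alphas), **d)


def _cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    female = _sex_params_from_dict(d.pop("female"))
    male = _sex_params_from_dict(d.pop("male"))
    shape = {sex: ShapeConstants(**sc) for sex, sc in d.pop("shape").items()}
    if "schedule" in d:
        d["schedule"] = tuple(d["schedule"])
    return CohortConfig(female=female, male=male, shape=shape, **d)


def load_config(path) -> AppConfig:
    """Load a YAML configuration file; omitted sections keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    cohort = (_cohort_config_from_dict(raw["cohort"])
              if "cohort" in raw else CohortConfig())
    fit_raw = dict(raw.get("fit", {}))
    for key in ("theta_starts", "theta_bounds", "sigma_bounds"):
        if key in fit_raw:
            fit_raw[key] = tuple(fit_raw[key])
    fit = FitOptions(**fit_raw)
    exclusion = ExclusionConfig(**raw.get("exclusion", {}))
    return AppConfig(cohort=cohort, fit=fit, exclusion=exclusion)


def config_hash(config: AppConfig) -> str:
    """Short stable hash of the full configuration, for run logs."""
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:12]
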