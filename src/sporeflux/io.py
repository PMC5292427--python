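"""File schemas: unit-suffixed CSV tables, key-value reports, configs.

Every numeric CSV column carries its unit as a suffix (``_h``, ``_mM``,
``_ppm``, ``_nM``, ``_per_ml``, ``_cm``, ``_yr``, ``_ml``); a numeric
column without a recognized suffix is rejected outright, because silent
unit mix-ups are the main failure mode of this kind of arithmetic.
Extra (unexpected but well-suffixed) columns are preserved with a
warning. Reports are flat ``key: value`` text files with repr-level
float precision so regression comparisons can be exact.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .growth import CARBON_ATOMS, SlurrySpec, TimeCourse
from .mpn import MPNDesign, TubeReading
from .synthetic import MPNScenario, ProfileScenario, SlurryScenario

__all__ = [
    "SchemaError",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_tubes_csv",
    "write_tubes_csv",
    "read_design_csv",
    "write_design_csv",
    "read_profile_csv",
    "write_profile_csv",
    "read_std_addition_csv",
    "write_std_addition_csv",
    "write_report",
    "read_report",
    "load_config",
    "scenarios_from_config",
]

UNIT_SUFFIXES = ("_h", "_mM", "_ppm", "_nM", "_per_ml", "_cm", "_yr", "_ml")
#: Columns that legitimately carry no unit suffix.
BARE_COLUMNS = {"sample_id", "level", "tubes", "positives", "detected", "signal"}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _validate_columns(
    df: pd.DataFrame,
    required: set[str],
    what: str,
    optional: set[str] = frozenset(),
) -> None:
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{what}: missing columns {sorted(missing)}")
    extra = []
    for col in df.columns:
        if col in required or col in optional or col in BARE_COLUMNS:
            continue
        if not col.endswith(UNIT_SUFFIXES):
            raise SchemaError(
                f"{what}: column {col!r} lacks a recognized unit suffix "
                f"{UNIT_SUFFIXES}"
            )
        extra.append(col)
    if extra:
        warnings.warn(f"{what}: preserving extra columns {extra}", stacklevel=3)


# --- tables ---------------------------------------------------------------

_TIMECOURSE_OPTIONAL = (
    {f"{sp}_mM" for sp in CARBON_ATOMS}
    | {"h2_ppm", "dpa_nM", "fish_cells_per_ml"}
)


def read_timecourse_csv(path: str | Path, slurry: SlurrySpec | None = None) -> TimeCourse:
    df = pd.read_csv(path)
    _validate_columns(df, {"time_h"}, f"time course {path}",
                      optional=_TIMECOURSE_OPTIONAL)
    return TimeCourse(data=df, slurry=slurry or SlurrySpec())


def write_timecourse_csv(tc: TimeCourse, path: str | Path) -> None:
    tc.data.to_csv(path, index=False)


def read_tubes_csv(path: str | Path) -> list[TubeReading]:
    df = pd.read_csv(path)
    _validate_columns(df, {"volume_ml", "acetate_mM"}, f"tube table {path}",
                      optional={"h2_ppm"})
    return [
        TubeReading(
            volume=float(r["volume_ml"]),
            acetate=float(r["acetate_mM"]),
            h2=float(r["h2_ppm"]) if "h2_ppm" in df.columns else None,
            dilution_level=int(r["level"]) if "level" in df.columns else None,
        )
        for _, r in df.iterrows()
    ]


def write_tubes_csv(tubes: pd.DataFrame, path: str | Path) -> None:
    _validate_columns(tubes, {"volume_ml", "acetate_mM"}, "tube table",
                      optional={"h2_ppm"})
    tubes.to_csv(path, index=False)


def read_design_csv(path: str | Path) -> MPNDesign:
    df = pd.read_csv(path)
    _validate_columns(df, {"volume_ml", "tubes", "positives"}, f"design {path}")
    return MPNDesign(
        volumes=tuple(df["volume_ml"].astype(float)),
        tubes=tuple(df["tubes"].astype(int)),
        positives=tuple(df["positives"].astype(int)),
    )


def write_design_csv(design: MPNDesign, path: str | Path) -> None:
    pd.DataFrame(
        {
            "volume_ml": design.volumes,
            "tubes": design.tubes,
            "positives": design.positives,
        }
    ).to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate_columns(
        df, {"depth_cm", "age_yr", "abundance_per_ml"}, f"profile {path}",
        optional={"ci_low_per_ml", "ci_high_per_ml"},
    )
    if "detected" not in df.columns:
        df["detected"] = True
    return df


def write_profile_csv(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, index=False)


def read_std_addition_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate_columns(df, {"added_nM", "signal"}, f"standard addition {path}")
    return df


def write_std_addition_csv(series: pd.DataFrame, path: str | Path) -> None:
    series.to_csv(path, index=False)


# --- reports --------------------------------------------------------------

def write_report(report: Mapping[str, Any], path: str | Path) -> None:
    """Write a flat key-value report, floats at repr precision."""
    import numbers

    lines = []
    for key, value in report.items():
        if isinstance(value, numbers.Real) and not isinstance(value, (bool, int)):
            rendered = repr(float(value))
        else:
            rendered = str(value)
        lines.append(f"{key}: {rendered}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(":")
        out[key.strip()] = value.strip()
    return out


# --- configs --------------------------------------------------------------

def load_config(path: str | Path) -> dict[str, Any]:
    """Load a structured-text (YAML ``key: value``) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path} must be a mapping")
    return cfg


_SCENARIO_TYPES = {
    "slurry": SlurryScenario,
    "mpn": MPNScenario,
    "profile": ProfileScenario,
}


def scenarios_from_config(cfg: Mapping[str, Any]) -> dict[str, Any]:
    """Build scenario objects from a config mapping with optional
    ``slurry``, ``mpn`` and ``profile`` sections (fields override the
    scenario defaults; tuple-valued fields accept YAML lists)."""
    out: dict[str, Any] = {}
    for key, cls in _SCENARIO_TYPES.items():
        if key in cfg:
            kwargs = dict(cfg[key])
            for field_name in ("volumes", "depths"):
                if field_name in kwargs:
                    kwargs[field_name] = tuple(kwargs[field_name])
            out[key] = cls(**kwargs)
    return out
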