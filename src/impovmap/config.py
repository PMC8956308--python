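"""YAML configuration handling and household-table I/O.

A household CSV can use arbitrary column names; a config maps logical
field names (total_expenditure, oop_payment, household_size,
survey_weight, district_id, covariates...) to the file's columns and
declares the currency/period of the expenditure fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .poverty import STANDARD_LINES, PovertyLine
from .simulate import GeneratorConfig

__all__ = [
    "load_yaml",
    "read_households",
    "parse_line",
    "generator_config_from_dict",
]


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def read_households(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a household CSV, renaming file columns to logical names.

    ``column_map`` maps logical name -> file column; unmapped columns
    pass through unchanged.
    """
    df = pd.read_csv(path)
    if column_map:
        missing = [c for c in column_map.values() if c not in df.columns]
        if missing:
            raise ValueError(f"household CSV lacks mapped columns: {missing}")
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def parse_line(spec: str | float, days_per_year: float = 365.0) -> PovertyLine:
    """A named standard line ('national', 'usd190', 'usd320') or a custom
    per-person-per-year amount."""
    if isinstance(spec, str) and spec in STANDARD_LINES:
        line = STANDARD_LINES[spec]
        if line.period == "per_day" and days_per_year != line.days_per_year:
            return PovertyLine(
                line.label, line.amount, line.period, line.currency, days_per_year
            )
        return line
    try:
        amount = float(spec)
    except (TypeError, ValueError):
        raise ValueError(
            f"unknown poverty line {spec!r}; use one of {sorted(STANDARD_LINES)} "
            "or a per-person-per-year amount"
        ) from None
    return PovertyLine(f"custom_{amount:g}", amount)


def generator_config_from_dict(d: dict[str, Any]) -> GeneratorConfig:
    d = dict(d)
    if "line" in d:
        d["line"] = parse_line(d["line"])
    if "households_per_district" in d and isinstance(d["households_per_district"], list):
        d["households_per_district"] = tuple(d["households_per_district"])
    return GeneratorConfig(**d)
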