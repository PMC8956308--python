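"""Weighted poverty and impoverishment statistics.

Households carry a total annual consumption expenditure, an annual
out-of-pocket (OOP) health payment, a size and a survey weight. All
population-level ratios weight each household by survey_weight *
household_size (person weighting), and compare per-capita expenditure
x_i with a per-person poverty line z:

    H   = 100 * sum w_i s_i 1{x_i < z} / sum w_i s_i      (head count, %)
    G   =       sum w_i s_i (z - x_i) 1{x_i < z} / sum w_i s_i  (gap, currency)
    NG  = 100 * G / z                                     (normalized gap, %)
    MPG = 100 * NG / H                                    (mean positive gap, %)

The impoverishing effect of OOP payments is the change in these
quantities when x_i is recomputed with the OOP payment deducted from
total expenditure (floored at zero). A household is flagged as
"impoverished by health payments" when it sits at or above the line
before deduction and strictly below it after.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PovertyLine",
    "PovertyMetrics",
    "ImpoverishmentTable",
    "NATIONAL_LINE",
    "USD190_LINE",
    "USD320_LINE",
    "STANDARD_LINES",
    "validate_households",
    "per_capita_expenditure",
    "compute_metrics",
    "impoverishment",
    "impoverishment_by_group",
    "binary_impoverishment_flag",
    "weighted_quintiles",
    "ses_dichotomy",
    "grouped_report_frame",
]

REQUIRED_COLUMNS = (
    "total_expenditure",
    "oop_payment",
    "household_size",
    "survey_weight",
)

METRIC_NAMES = ("head_count_pct", "poverty_gap", "normalized_gap_pct", "mean_positive_gap_pct")


@dataclass(frozen=True)
class PovertyLine:
    """A poverty threshold in currency per person, per year or per day."""

    label: str
    amount: float
    period: str = "per_year"
    currency: str = "MWK"
    days_per_year: float = 365.0

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("poverty line amount must be positive")
        if self.period not in ("per_year", "per_day"):
            raise ValueError("period must be 'per_year' or 'per_day'")

    @property
    def per_year(self) -> float:
        """Annualised threshold; per-day lines convert once, by days_per_year."""
        if self.period == "per_day":
            return self.amount * self.days_per_year
        return self.amount


# Malawi 2016/17 thresholds: the national line, and the US$1.90 / US$3.20
# (2011 PPP) international lines expressed in 2016 MWK per person per day.
NATIONAL_LINE = PovertyLine("national", 137_425.0)
USD190_LINE = PovertyLine("usd190", 526.2, period="per_day")
USD320_LINE = PovertyLine("usd320", 886.2, period="per_day")
STANDARD_LINES = {ln.label: ln for ln in (NATIONAL_LINE, USD190_LINE, USD320_LINE)}


@dataclass(frozen=True)
class PovertyMetrics:
    head_count_pct: float
    poverty_gap: float
    normalized_gap_pct: float
    mean_positive_gap_pct: float  # NaN when head count is zero (0/0)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass(frozen=True)
class ImpoverishmentTable:
    """Pre/post-payment metrics with absolute and relative differences."""

    pre: PovertyMetrics
    post: PovertyMetrics
    absolute_diff: dict[str, float] = field(init=False)
    relative_diff_pct: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        absolute, relative = {}, {}
        for m in METRIC_NAMES:
            a, b = getattr(self.pre, m), getattr(self.post, m)
            absolute[m] = b - a
            relative[m] = (b - a) / a * 100.0 if a != 0 else np.nan
        object.__setattr__(self, "absolute_diff", absolute)
        object.__setattr__(self, "relative_diff_pct", relative)

    def to_frame(self) -> pd.DataFrame:
        """Full-precision tidy table (metric, pre, post, absolute, relative)."""
        return pd.DataFrame(
            {
                "metric": METRIC_NAMES,
                "pre": [getattr(self.pre, m) for m in METRIC_NAMES],
                "post": [getattr(self.post, m) for m in METRIC_NAMES],
                "absolute": [self.absolute_diff[m] for m in METRIC_NAMES],
                "relative_pct": [self.relative_diff_pct[m] for m in METRIC_NAMES],
            }
        )

    def to_report_frame(self, ndigits: int = 2) -> pd.DataFrame:
        """Publication-style table: metrics rounded first, differences derived
        from the rounded values (the convention such survey tables print)."""
        rows = []
        for m in METRIC_NAMES:
            pre = round(getattr(self.pre, m), ndigits)
            post = round(getattr(self.post, m), ndigits)
            absolute = round(post - pre, ndigits)
            relative = round(absolute / pre * 100.0, ndigits) if pre != 0 else np.nan
            rows.append((m, pre, post, absolute, relative))
        return pd.DataFrame(
            rows, columns=["metric", "pre", "post", "absolute", "relative_pct"]
        )


def validate_households(df: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants every downstream operation assumes."""
    if len(df) == 0:
        raise ValueError("empty household table")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"household table lacks required columns: {missing}")
    if (df["household_size"] < 1).any():
        raise ValueError("household_size must be >= 1 for every household")
    if (df["survey_weight"] <= 0).any():
        raise ValueError("survey_weight must be positive for every household")
    if (df["total_expenditure"] < 0).any() or (df["oop_payment"] < 0).any():
        raise ValueError("expenditures and OOP payments must be nonnegative")
    return df


def per_capita_expenditure(
    total_expenditure, oop_payment, household_size, deduct_oop: bool = False
):
    """Per-capita annual expenditure, optionally net of OOP health payments.

    Net expenditure is floored at zero so a poverty gap is never computed
    from negative consumption. Accepts scalars or aligned arrays.
    """
    total = np.asarray(total_expenditure, dtype=float)
    oop = np.asarray(oop_payment, dtype=float)
    size = np.asarray(household_size, dtype=float)
    if np.any(size < 1):
        raise ValueError("household_size must be >= 1")
    net = np.maximum(total - oop, 0.0) if deduct_oop else total
    x = net / size
    return float(x) if x.ndim == 0 else x


def compute_metrics(
    df: pd.DataFrame,
    line: PovertyLine,
    deduct_oop: bool = False,
    strict: bool = True,
) -> PovertyMetrics:
    """Person-weighted H, G, NG, MPG for one poverty line.

    ``strict`` controls the poor/non-poor boundary: x < z when True
    (ties count as non-poor, the default), x <= z when False.
    """
    validate_households(df)
    z = line.per_year
    x = per_capita_expenditure(
        df["total_expenditure"], df["oop_payment"], df["household_size"], deduct_oop
    )
    pw = (df["survey_weight"] * df["household_size"]).to_numpy(dtype=float)
    poor = x < z if strict else x <= z
    total_w = pw.sum()
    H = 100.0 * float(pw[poor].sum()) / total_w
    G = float((pw * (z - x) * poor).sum()) / total_w
    NG = 100.0 * G / z
    if H > 0:
        MPG = 100.0 * NG / H
    else:
        warnings.warn(
            "head count is zero; mean positive gap undefined (reported as NaN)",
            stacklevel=2,
        )
        MPG = np.nan
    return PovertyMetrics(H, G, NG, MPG)


def impoverishment(
    df: pd.DataFrame, line: PovertyLine, strict: bool = True
) -> ImpoverishmentTable:
    """Pre/post-payment metric table for one poverty line."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-H warning surfaces via NaN in table
        pre = compute_metrics(df, line, deduct_oop=False, strict=strict)
        post = compute_metrics(df, line, deduct_oop=True, strict=strict)
    return ImpoverishmentTable(pre, post)


def weighted_quintiles(df: pd.DataFrame) -> pd.Series:
    """Quintile (1..5) of per-capita pre-payment expenditure.

    Cuts fall at cumulative person-weight 20/40/60/80%; households with
    tied expenditure all take the lower quintile.
    """
    validate_households(df)
    x = per_capita_expenditure(
        df["total_expenditure"], df["oop_payment"], df["household_size"], False
    )
    pw = (df["survey_weight"] * df["household_size"]).to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    cum_before = _cum_share_before_block(x[order], pw[order])
    q_sorted = np.searchsorted([0.2, 0.4, 0.6, 0.8], cum_before, side="right") + 1
    q = np.empty(len(df), dtype=int)
    q[order] = q_sorted
    return pd.Series(q, index=df.index, name="quintile")


def _cum_share_before_block(x_sorted: np.ndarray, pw_sorted: np.ndarray) -> np.ndarray:
    """Cumulative person-weight share strictly below each household's
    expenditure value (constant within a tie block)."""
    total = pw_sorted.sum()
    cum = np.concatenate([[0.0], np.cumsum(pw_sorted)[:-1]]) / total
    # within a tie block, everyone uses the block-start cumulative share
    block_start = np.zeros(len(x_sorted), dtype=int)
    for i in range(1, len(x_sorted)):
        block_start[i] = block_start[i - 1] if x_sorted[i] == x_sorted[i - 1] else i
    return cum[block_start]


def ses_dichotomy(df: pd.DataFrame, cut: float = 0.5) -> pd.Series:
    """Lower/higher socio-economic status by per-capita pre-payment
    expenditure, split at cumulative person-weight share ``cut``."""
    x = per_capita_expenditure(
        df["total_expenditure"], df["oop_payment"], df["household_size"], False
    )
    pw = (df["survey_weight"] * df["household_size"]).to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    cum_before = _cum_share_before_block(x[order], pw[order])
    lab_sorted = np.where(cum_before < cut, "lower", "higher")
    lab = np.empty(len(df), dtype=object)
    lab[order] = lab_sorted
    return pd.Series(lab, index=df.index, name="ses")


def impoverishment_by_group(
    df: pd.DataFrame,
    line: PovertyLine,
    grouping: str,
    strict: bool = True,
    ses_cut: float = 0.5,
) -> dict[str, ImpoverishmentTable]:
    """One pre/post table per level of a grouping variable.

    ``grouping`` is a column name (e.g. ``district_id``, ``region``,
    ``rural``), or the derived groupings ``quintile`` / ``ses``.
    Quintiles are formed on weighted per-capita pre-payment expenditure
    over the full table before splitting.
    """
    validate_households(df)
    if grouping == "quintile":
        key = weighted_quintiles(df)
    elif grouping == "ses":
        key = ses_dichotomy(df, cut=ses_cut)
    elif grouping in df.columns:
        key = df[grouping]
    else:
        raise KeyError(f"unknown grouping variable {grouping!r}")
    out: dict[str, ImpoverishmentTable] = {}
    for level, sub in df.groupby(key, sort=True, observed=True):
        out[str(level)] = impoverishment(sub, line, strict=strict)
    return out


def grouped_report_frame(
    tables: Mapping[str, ImpoverishmentTable], ndigits: int = 2
) -> pd.DataFrame:
    """Tidy CSV-ready frame across groups (group, metric, pre, post, ...)."""
    frames = []
    for group, tab in tables.items():
        f = tab.to_report_frame(ndigits)
        f.insert(0, "group", group)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def binary_impoverishment_flag(
    df: pd.DataFrame,
    line: PovertyLine,
    include_deepening: bool = False,
    strict: bool = True,
) -> np.ndarray:
    """1 iff the household crossed the line because of OOP payments.

    A household crosses when per-capita pre-payment expenditure is at or
    above the line and the post-payment value is below it; already-poor
    households are 0 unless ``include_deepening`` also counts those
    pushed strictly deeper below the line.
    """
    validate_households(df)
    z = line.per_year
    pre = per_capita_expenditure(
        df["total_expenditure"], df["oop_payment"], df["household_size"], False
    )
    post = per_capita_expenditure(
        df["total_expenditure"], df["oop_payment"], df["household_size"], True
    )
    pre = np.atleast_1d(pre)
    post = np.atleast_1d(post)
    poor_pre = pre < z if strict else pre <= z
    poor_post = post < z if strict else post <= z
    flag = (~poor_pre) & poor_post
    if include_deepening:
        flag |= poor_pre & (post < pre)
    return flag.astype(int)
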