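"""Readers, writers and validation for food-balance, impact, HDI and population tables.

All tables are plain pandas DataFrames with a fixed, validated schema. The
canonical on-disk dialect is UTF-8 comma-separated text with a header row and
period decimal separator; an empty cell means "missing". Country identifiers
are opaque strings.

Food tables are "wide": one row per (country, year), one column per food
group in kcal/capita/day plus the total supply. A long-format reader
(country, year, variable, value) is provided for FAOSTAT-style exports and
normalised to wide.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 11 food groups whose per-capita calorie supplies, together with the
#: total supply, form the 12 clustering variables.
FOOD_GROUPS: tuple[str, ...] = (
    "animal_products",
    "cereals",
    "pulses",
    "starchy_roots",
    "oilcrops",
    "vegetable_oils",
    "vegetables",
    "fruits",
    "sugar_sweeteners",
    "sugarcrops",
    "alcoholic_beverages",
)

#: Column order of a canonical wide food table.
FOOD_COLUMNS: tuple[str, ...] = ("country", "year") + FOOD_GROUPS + ("total_kcal",)

#: Impact-table value columns (any of these may be missing per row).
IMPACT_VALUE_COLUMNS: tuple[str, ...] = (
    "oi_ratio",
    "crop_nonco2_g",
    "livestock_nonco2_g",
    "crop_prod_kcal",
    "animal_prod_kcal",
    "feed_kcal",
    "population",
)

IMPACT_COLUMNS: tuple[str, ...] = ("country", "year") + IMPACT_VALUE_COLUMNS

#: Absolute slack (kcal/cap/day) allowed for the group sum to overshoot the
#: total. The groups cover most but not all of the food supply, so a positive
#: remainder ("Others") is expected; only an overshoot beyond rounding noise
#: is treated as an error.
GROUP_SUM_SLACK_KCAL = 1.0
GROUP_SUM_REL_SLACK = 1e-6


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unusable header."""


class ValidationError(ValueError):
    """A table parsed but contains invalid values; message locates the rows."""


@dataclass(frozen=True)
class FoodRecord:
    """One country-year of per-capita food supply (kcal/cap/day)."""

    country: str
    year: int
    group_kcal: dict[str, float]
    total_kcal: float


@dataclass(frozen=True)
class ImpactRecord:
    """One country-year of agricultural impact data; ``None`` marks missing."""

    country: str
    year: int
    oi_ratio: float | None = None
    crop_nonco2_g: float | None = None
    livestock_nonco2_g: float | None = None
    crop_prod_kcal: float | None = None
    animal_prod_kcal: float | None = None
    feed_kcal: float | None = None
    population: float | None = None


@dataclass
class ValidationReport:
    """Per-field missingness summary for an impact table."""

    n_records: int
    missing: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    @property
    def flagged(self) -> list[tuple[str, int]]:
        keys: set[tuple[str, int]] = set()
        for rows in self.missing.values():
            keys.update(rows)
        return sorted(keys)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing mandatory column(s): {', '.join(missing)}")


def _check_duplicates(df: pd.DataFrame, what: str) -> None:
    dup = df.duplicated(subset=["country", "year"])
    if dup.any():
        rows = df.loc[dup, ["country", "year"]].itertuples(index=False)
        keys = ", ".join(f"({c}, {y})" for c, y in list(rows)[:5])
        raise ValidationError(f"{what} has duplicate (country, year) keys: {keys}")


def _read_csv(path_or_buf) -> pd.DataFrame:
    return pd.read_csv(path_or_buf, dtype={"country": str})


def read_food_table(path_or_buf, year_range: tuple[int, int] | None = None) -> pd.DataFrame:
    """Read and validate a wide food-balance table.

    Parameters
    ----------
    path_or_buf
        Path or file-like object of a canonical CSV with columns
        ``country, year, <11 food groups>, total_kcal``.
    year_range
        Optional inclusive (lo, hi); years outside raise ``ValidationError``.

    Returns
    -------
    DataFrame with canonical column order, one row per (country, year).
    """
    df = _read_csv(path_or_buf)
    _require_columns(df, FOOD_COLUMNS, "food table")
    df = df.loc[:, list(FOOD_COLUMNS)].copy()
    df["year"] = df["year"].astype(int)
    _check_duplicates(df, "food table")

    values = df[list(FOOD_GROUPS) + ["total_kcal"]]
    if values.isna().any().any():
        bad = values.isna().any(axis=1)
        raise ValidationError(
            f"food table has missing calorie values at rows {list(df.index[bad])[:5]}"
        )
    neg = (values < 0).any(axis=1)
    if neg.any():
        raise ValidationError(
            f"food table has negative calorie values at rows {list(df.index[neg])[:5]}"
        )
    group_sum = df[list(FOOD_GROUPS)].sum(axis=1)
    limit = df["total_kcal"] * (1.0 + GROUP_SUM_REL_SLACK) + GROUP_SUM_SLACK_KCAL
    over = group_sum > limit
    if over.any():
        raise ValidationError(
            "food group sum exceeds total_kcal beyond slack at rows "
            f"{list(df.index[over])[:5]}"
        )
    if year_range is not None:
        lo, hi = year_range
        out = ~df["year"].between(lo, hi)
        if out.any():
            raise ValidationError(
                f"years outside configured range [{lo}, {hi}] at rows {list(df.index[out])[:5]}"
            )
    return df.reset_index(drop=True)


def read_long_food_table(path_or_buf, **kwargs) -> pd.DataFrame:
    """Read a long-format food table (country, year, variable, value) and pivot to wide."""
    df = _read_csv(path_or_buf)
    _require_columns(df, ("country", "year", "variable", "value"), "long food table")
    wide = df.pivot_table(
        index=["country", "year"], columns="variable", values="value", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    buf = io.StringIO()
    wide.to_csv(buf, index=False)
    buf.seek(0)
    return read_food_table(buf, **kwargs)


def write_food_table(df: pd.DataFrame, path) -> None:
    """Write a food table in the canonical dialect (round-trips byte-identically)."""
    df.loc[:, list(FOOD_COLUMNS)].to_csv(path, index=False)


def food_records(df: pd.DataFrame) -> list[FoodRecord]:
    """Materialise a validated food table as :class:`FoodRecord` objects."""
    return [
        FoodRecord(
            country=row.country,
            year=int(row.year),
            group_kcal={g: float(getattr(row, g)) for g in FOOD_GROUPS},
            total_kcal=float(row.total_kcal),
        )
        for row in df.itertuples(index=False)
    ]


def others_kcal(record: FoodRecord | pd.Series) -> float:
    """Residual ("Others") calories: total minus the 11 explicit groups.

    Clamped to zero (with a warning) when the group sum overshoots the total
    within the permitted slack.
    """
    if isinstance(record, FoodRecord):
        total = record.total_kcal
        group_sum = sum(record.group_kcal.values())
    else:
        total = float(record["total_kcal"])
        group_sum = float(sum(record[g] for g in FOOD_GROUPS))
    rest = total - group_sum
    if rest < 0:
        warnings.warn(
            f"group sum {group_sum:.3f} exceeds total {total:.3f} within slack; "
            "clamping Others to 0",
            stacklevel=2,
        )
        return 0.0
    return rest


def read_impact_table(path_or_buf) -> pd.DataFrame:
    """Read an impact table; empty cells stay NaN (missing, flagged downstream)."""
    df = _read_csv(path_or_buf)
    _require_columns(df, ("country", "year"), "impact table")
    for col in IMPACT_VALUE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df.loc[:, list(IMPACT_COLUMNS)].copy()
    df["year"] = df["year"].astype(int)
    _check_duplicates(df, "impact table")
    return df.reset_index(drop=True)


def write_impact_table(df: pd.DataFrame, path) -> None:
    df.loc[:, list(IMPACT_COLUMNS)].to_csv(path, index=False)


def validate_impacts(df: pd.DataFrame) -> ValidationReport:
    """Validate an impact table and report per-field missingness.

    Records with missing fields are retained but flagged, so pattern-level
    averages can restrict to the members with data for each variable.
    A non-positive output/input ratio is an error (it is a divisor).
    """
    _require_columns(df, IMPACT_COLUMNS, "impact table")
    for col in IMPACT_VALUE_COLUMNS:
        vals = df[col]
        neg = vals.notna() & (vals < 0)
        if neg.any():
            raise ValidationError(
                f"negative {col} at rows {list(df.index[neg])[:5]}"
            )
    bad_r = df["oi_ratio"].notna() & (df["oi_ratio"] <= 0)
    if bad_r.any():
        raise ValidationError(
            f"oi_ratio must be > 0; zero found at rows {list(df.index[bad_r])[:5]}"
        )
    report = ValidationReport(n_records=len(df))
    for col in IMPACT_VALUE_COLUMNS:
        na = df[col].isna()
        if na.any():
            report.missing[col] = [
                (str(c), int(y))
                for c, y in df.loc[na, ["country", "year"]].itertuples(index=False)
            ]
    return report


def read_hdi_table(path_or_buf) -> pd.DataFrame:
    """Read an HDI table (country, year, hdi with hdi in [0, 1])."""
    df = _read_csv(path_or_buf)
    _require_columns(df, ("country", "year", "hdi"), "HDI table")
    df = df.loc[:, ["country", "year", "hdi"]].copy()
    df["year"] = df["year"].astype(int)
    _check_duplicates(df, "HDI table")
    bad = df["hdi"].notna() & ~df["hdi"].between(0.0, 1.0)
    if bad.any():
        raise ValidationError(f"hdi outside [0, 1] at rows {list(df.index[bad])[:5]}")
    return df.reset_index(drop=True)


def read_population_table(path_or_buf) -> pd.DataFrame:
    """Read a population table (country, year, population >= 0)."""
    df = _read_csv(path_or_buf)
    _require_columns(df, ("country", "year", "population"), "population table")
    df = df.loc[:, ["country", "year", "population"]].copy()
    df["year"] = df["year"].astype(int)
    _check_duplicates(df, "population table")
    neg = df["population"].notna() & (df["population"] < 0)
    if neg.any():
        raise ValidationError(f"negative population at rows {list(df.index[neg])[:5]}")
    return df.reset_index(drop=True)
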