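"""Embodied fossil-energy and GHG accounting for dietary patterns.

The accounting chain, per dietary pattern z (all energies in kcal/cap/day,
intensities in g CO2eq/kcal, emissions in kg CO2eq/cap/day):

    ec, ea   non-CO2 emission intensity of crop / animal production,
             computed per country-year as emissions over produced calories;
    EC_z  = PC_z * ec_z / 1000            crop non-CO2 emissions
    EA_z  = (PA_z * ea_z + F_z * ec_z) / 1000
                                          livestock non-CO2 emissions,
                                          charging feed at crop intensity
    FE_z  = (PC_z + F_z) / R_z            fossil energy input, with R the
                                          agricultural energy output/input ratio
    E_fossil_z = FE_z * e_d / 1000        fossil-fuel CO2, with e_d the diesel
                                          emission intensity (0.36 g CO2eq/kcal)
    ET_z  = EC_z + EA_z + E_fossil_z      total embodied emissions

PC is crop-product consumption (total food supply minus animal products,
"Others" included); PA is animal-product consumption; F is feed use.

Pattern inputs are averaged over the members of each pattern that have data
for the given variable (the S'_z subsets); a pattern with no data for a
variable gets N/A, never infinity. Because averaging and the nonlinear FE
division do not commute, the table is emitted in two variants: equations
applied to pattern-mean inputs (default) and equations applied per
country-year then averaged.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FOOD_GROUPS

#: Diesel emission intensity, g CO2eq per kcal of fossil energy.
E_D = 0.36


class EmissionError(ValueError):
    pass


def intensities(
    crop_nonco2_g: float, crop_prod_kcal: float,
    livestock_nonco2_g: float, animal_prod_kcal: float,
) -> tuple[float, float]:
    """Per-kcal non-CO2 intensities (ec, ea); NaN when a denominator is 0/missing."""
    ec = (
        crop_nonco2_g / crop_prod_kcal
        if _ok(crop_nonco2_g) and _ok(crop_prod_kcal) and crop_prod_kcal > 0
        else math.nan
    )
    ea = (
        livestock_nonco2_g / animal_prod_kcal
        if _ok(livestock_nonco2_g) and _ok(animal_prod_kcal) and animal_prod_kcal > 0
        else math.nan
    )
    return ec, ea


def _ok(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


def feed_energy(
    feed_item_masses: dict[str, float],
    nutritive_factors: dict[str, float],
    population: float,
) -> float:
    """Per-capita daily feed energy from annual per-item feed masses.

    F = Σ_items mass * kcal-per-mass / (population * 365).
    """
    if population <= 0:
        raise EmissionError("population must be > 0")
    total = 0.0
    for item, mass in feed_item_masses.items():
        if item not in nutritive_factors:
            raise EmissionError(f"no nutritive factor for feed item {item!r}")
        total += mass * nutritive_factors[item]
    return total / (population * 365.0)


def pattern_average(values, members) -> tuple[float, int]:
    """Mean over the members with data (the S'_z rule).

    ``values`` maps (country, year) → value (NaN/None = missing); ``members``
    is the pattern's membership set. Returns (mean, n_used); (NaN, 0) when no
    member has data.
    """
    avail = [values[m] for m in members if m in values and _ok(values[m])]
    if not avail:
        return math.nan, 0
    return float(np.mean(avail)), len(avail)


def crop_emissions(pc: float, ec: float) -> float:
    """EC = PC * ec / 1000, kg CO2eq/cap/day."""
    return pc * ec / 1000.0


def animal_emissions(pa: float, ea: float, feed: float, ec: float) -> float:
    """EA = (PA * ea + F * ec) / 1000: direct livestock non-CO2 plus the
    feed's crop-intensity burden, kg CO2eq/cap/day."""
    return (pa * ea + feed * ec) / 1000.0


def fossil_energy(pc: float, feed: float, oi_ratio: float) -> float:
    """FE = (PC + F) / R, kcal/cap/day; NaN propagates from a missing R."""
    if _ok(oi_ratio) and oi_ratio <= 0:
        raise EmissionError("energy output/input ratio must be > 0")
    return (pc + feed) / oi_ratio


def total_emissions(
    ec_emis: float, ea_emis: float, fe: float, e_d: float = E_D
) -> tuple[float, float]:
    """(E_fossil, ET): fossil CO2 = FE * e_d / 1000; ET = EC + EA + E_fossil."""
    fossil = fe * e_d / 1000.0
    return fossil, ec_emis + ea_emis + fossil


@dataclass(frozen=True)
class CountryYearIntensity:
    """Per-country-year inputs of the accounting chain (NaN = missing)."""

    country: str
    year: int
    pc: float
    pa: float
    ec: float
    ea: float
    oi_ratio: float
    feed: float


def country_intensities(food: pd.DataFrame, impacts: pd.DataFrame) -> pd.DataFrame:
    """Join food and impact tables into per-country-year accounting inputs."""
    f = food[["country", "year", "animal_products", "total_kcal"]].copy()
    f["pa"] = f["animal_products"]
    f["pc"] = f["total_kcal"] - f["animal_products"]
    merged = f[["country", "year", "pc", "pa"]].merge(
        impacts, on=["country", "year"], how="left"
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["ec"] = np.where(
            merged["crop_prod_kcal"] > 0,
            merged["crop_nonco2_g"] / merged["crop_prod_kcal"],
            np.nan,
        )
        merged["ea"] = np.where(
            merged["animal_prod_kcal"] > 0,
            merged["livestock_nonco2_g"] / merged["animal_prod_kcal"],
            np.nan,
        )
    return merged[["country", "year", "pc", "pa", "ec", "ea", "oi_ratio", "feed_kcal"]]


_AVERAGED_VARS = ("pc", "pa", "feed_kcal", "ec", "ea", "oi_ratio")


def build_pattern_table(
    labels: pd.DataFrame,
    food: pd.DataFrame,
    impacts: pd.DataFrame,
    e_d: float = E_D,
    n_patterns: int | None = None,
) -> pd.DataFrame:
    """The per-pattern impact table, in both averaging orders.

    Columns ``pc..total_emis`` apply the accounting equations to pattern-mean
    inputs; the ``*_cl`` columns average per-country-year results instead
    (restricted to members with complete inputs). ``n_<var>`` counts the
    members used for each averaged input.
    """
    ci = country_intensities(food, impacts)
    merged = labels.merge(ci, on=["country", "year"], how="left", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", ["country", "year"]]
        raise EmissionError(
            "labels without joined records: "
            + ", ".join(f"({c}, {y})" for c, y in bad.head(5).itertuples(index=False))
        )
    merged = merged.drop(columns="_merge")

    # country-level variant: full chain per member, then averaged
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["_ec_emis"] = crop_emissions(merged["pc"], merged["ec"])
        merged["_ea_emis"] = animal_emissions(
            merged["pa"], merged["ea"], merged["feed_kcal"], merged["ec"]
        )
        merged["_fe"] = (merged["pc"] + merged["feed_kcal"]) / merged["oi_ratio"]
        merged["_fossil"] = merged["_fe"] * e_d / 1000.0
        merged["_total"] = merged["_ec_emis"] + merged["_ea_emis"] + merged["_fossil"]

    rows = []
    n_pat = n_patterns or int(labels["pattern"].max())
    for z in range(1, n_pat + 1):
        sub = merged[merged["pattern"] == z]
        row: dict = dict(pattern=z, n_members=len(sub))
        for var in _AVERAGED_VARS:
            vals = sub[var].dropna()
            row[var] = float(vals.mean()) if len(vals) else math.nan
            row[f"n_{var}"] = int(len(vals))
        if row["n_members"] and not math.isnan(row["ec"]):
            ec_emis = crop_emissions(row["pc"], row["ec"])
            ea_emis = animal_emissions(row["pa"], row["ea"], row["feed_kcal"], row["ec"])
            fe = fossil_energy(row["pc"], row["feed_kcal"], row["oi_ratio"])
            fossil, total = total_emissions(ec_emis, ea_emis, fe, e_d)
        else:
            ec_emis = ea_emis = fe = fossil = total = math.nan
        row.update(
            fe=fe, ec_emis=ec_emis, ea_emis=ea_emis, fossil_emis=fossil, total_emis=total
        )
        for col, src in (
            ("fe_cl", "_fe"),
            ("ec_emis_cl", "_ec_emis"),
            ("ea_emis_cl", "_ea_emis"),
            ("fossil_emis_cl", "_fossil"),
            ("total_emis_cl", "_total"),
        ):
            vals = sub[src].dropna()
            row[col] = float(vals.mean()) if len(vals) else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def pattern_table_from_inputs(inputs: pd.DataFrame, e_d: float = E_D) -> pd.DataFrame:
    """Run the accounting equations on already-averaged per-pattern inputs.

    ``inputs`` needs columns pattern, pc_kcal, pa_kcal, feed_kcal,
    ec_g_per_kcal, ea_g_per_kcal, oi_ratio and optionally fe_kcal (used as-is
    for the fossil term when present — matching a table whose fossil-energy
    column was computed upstream). Rows with missing intensities yield NaN.
    """
    rows = []
    for r in inputs.itertuples(index=False):
        pc, pa, feed = r.pc_kcal, r.pa_kcal, r.feed_kcal
        ec, ea = r.ec_g_per_kcal, r.ea_g_per_kcal
        if not (_ok(ec) and _ok(ea) and _ok(r.oi_ratio)):
            rows.append(
                dict(pattern=r.pattern, fe=math.nan, ec_emis=math.nan,
                     ea_emis=math.nan, fossil_emis=math.nan, total_emis=math.nan)
            )
            continue
        fe = getattr(r, "fe_kcal", math.nan)
        if not _ok(fe):
            fe = fossil_energy(pc, feed, r.oi_ratio)
        ec_emis = crop_emissions(pc, ec)
        ea_emis = animal_emissions(pa, ea, feed, ec)
        fossil, total = total_emissions(ec_emis, ea_emis, fe, e_d)
        rows.append(
            dict(pattern=r.pattern, fe=fe, ec_emis=ec_emis, ea_emis=ea_emis,
                 fossil_emis=fossil, total_emis=total)
        )
    return pd.DataFrame(rows)


def reference_pattern_table() -> pd.DataFrame:
    """The published per-pattern impact table of the sixteen global dietary
    patterns (pattern 9 has no intensity/energy data)."""
    ref = importlib.resources.files("dietghg.data") / "reference_pattern_table.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
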