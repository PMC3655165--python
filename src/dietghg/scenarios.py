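"""HDI–consumption model and the emission projection scenarios.

Consumption of total food, animal products, sweeteners, vegetable oils and
vegetables rises exponentially with the Human Development Index:
``ln(consumption) = a + b * HDI``, fitted by ordinary least squares on
pattern-year mean points. Three projection scenarios combine this relation
with population and HDI trajectories:

* **A** — population growth only: per-capita diets and intensities frozen at
  the base year; global totals scale linearly with population.
* **B** — population growth plus diet change: each country's total and
  animal-product consumption evolve along its HDI path via the fitted
  exponential relations (feed scales with animal products at the base-year
  feed-to-animal ratio); emission intensities stay frozen.
* **C** — as B, plus technology and management: non-CO2 intensities and the
  energy output/input ratio are replaced by a best-practice policy (by
  default the base-year means of the most efficient, very-high-calorie
  pattern group).

Projected per-capita totals are capped (default 3,460 kcal/cap/day, just
above the highest observed diet) because the fitted exponential is unbounded
as HDI → 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .emissions import E_D
from .tables import FOOD_GROUPS

logger = logging.getLogger(__name__)

#: Diet components with an HDI relation (total + four food groups).
HDI_COMPONENTS = (
    "total",
    "animal_products",
    "sugar_sweeteners",
    "vegetable_oils",
    "vegetables",
)

#: Default per-capita consumption ceiling for projections, kcal/cap/day.
CONSUMPTION_CAP = 3460.0


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class HdiFit:
    """OLS fit of ln(consumption) on HDI for one diet component."""

    component: str
    intercept: float
    slope: float
    n: int
    resid_sd: float
    se_intercept: float
    se_slope: float


def fit_hdi_relation(hdi, consumption, component: str = "total") -> HdiFit:
    """Least-squares fit of ``ln(consumption) = a + b * HDI``."""
    hdi = np.asarray(hdi, dtype=float)
    cons = np.asarray(consumption, dtype=float)
    if len(hdi) != len(cons) or len(hdi) < 3:
        raise ScenarioError("need at least 3 (HDI, consumption) points")
    if (cons <= 0).any():
        raise ScenarioError("consumption must be positive (log model)")
    if np.std(hdi) == 0:
        raise ScenarioError("degenerate HDI spread: all points identical")
    res = sm.OLS(np.log(cons), sm.add_constant(hdi)).fit()
    return HdiFit(
        component=component,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        n=int(res.nobs),
        resid_sd=float(np.sqrt(res.scale)),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
    )


def predict_consumption(fit: HdiFit, hdi: float, cap: float | None = None) -> float:
    """exp(a + b * HDI), optionally capped; HDI must lie in [0, 1]."""
    if not 0.0 <= hdi <= 1.0:
        raise ScenarioError(f"HDI {hdi} outside [0, 1]")
    value = math.exp(fit.intercept + fit.slope * hdi)
    return min(value, cap) if cap is not None else value


def pattern_year_points(
    labels: pd.DataFrame, food: pd.DataFrame, hdi: pd.DataFrame, component: str
) -> pd.DataFrame:
    """Pattern-year mean (HDI, consumption) points for fitting a component."""
    col = "total_kcal" if component == "total" else component
    if component != "total" and component not in FOOD_GROUPS:
        raise ScenarioError(f"unknown component {component!r}")
    m = labels.merge(food[["country", "year", col]], on=["country", "year"]).merge(
        hdi, on=["country", "year"]
    )
    pts = (
        m.groupby(["pattern", "year"])
        .agg(hdi=("hdi", "mean"), consumption=(col, "mean"))
        .reset_index()
    )
    return pts[pts["consumption"] > 0]


def fit_components(
    labels: pd.DataFrame, food: pd.DataFrame, hdi: pd.DataFrame
) -> dict[str, HdiFit]:
    """Fit the HDI relation for every modeled component."""
    return {
        comp: fit_hdi_relation(
            *(lambda p: (p["hdi"], p["consumption"]))(
                pattern_year_points(labels, food, hdi, comp)
            ),
            component=comp,
        )
        for comp in HDI_COMPONENTS
    }


@dataclass(frozen=True)
class BestPractice:
    """Intensity policy for Scenario C: replacement ec, ea and O/I ratio."""

    ec: float
    ea: float
    oi_ratio: float


def best_practice_policy(pattern_table: pd.DataFrame, pattern_ids) -> BestPractice:
    """Mean intensities of the given patterns (typically the very-high group)."""
    sub = pattern_table[pattern_table["pattern"].isin(list(pattern_ids))]
    if sub.empty:
        raise ScenarioError("no patterns matched the best-practice selection")
    return BestPractice(
        ec=float(sub["ec"].mean()),
        ea=float(sub["ea"].mean()),
        oi_ratio=float(sub["oi_ratio"].mean()),
    )


@dataclass
class ScenarioSpec:
    """One projection run. ``population``/``hdi`` are (country, year, value)
    tables covering base_year..horizon_year (HDI required for B and C)."""

    kind: str
    base_year: int
    population: pd.DataFrame
    hdi: pd.DataFrame | None = None
    horizon_year: int = 2050
    policy: BestPractice | None = None
    cap: float = CONSUMPTION_CAP
    e_d: float = E_D

    def __post_init__(self):
        if self.kind not in ("A", "B", "C"):
            raise ScenarioError(f"scenario kind must be A, B or C, got {self.kind!r}")
        if self.kind == "C" and self.policy is None:
            raise ScenarioError("Scenario C requires a best-practice policy")
        if self.kind in ("B", "C") and self.hdi is None:
            raise ScenarioError(f"Scenario {self.kind} requires HDI series")
        if self.horizon_year < self.base_year:
            raise ScenarioError("horizon before base year")


#: Joule content of one kcal (thermochemical), for EJ/yr conversion.
J_PER_KCAL = 4184.0


def global_aggregate(percap_kg_day: np.ndarray, population: np.ndarray) -> float:
    """Σ_c percap_c × pop_c × 365, converted from kg/yr to Gt CO2eq/yr."""
    return float(np.sum(np.asarray(percap_kg_day) * np.asarray(population)) * 365.0 / 1e12)


def _series_matrix(df: pd.DataFrame, value: str, countries, years) -> pd.DataFrame:
    pivot = df.pivot(index="country", columns="year", values=value)
    missing_c = [c for c in countries if c not in pivot.index]
    if missing_c:
        raise ScenarioError(f"{value} series missing for countries: {missing_c[:5]}")
    pivot = pivot.loc[countries, :]
    missing_y = [y for y in years if y not in pivot.columns or pivot[y].isna().any()]
    if missing_y:
        raise ScenarioError(f"{value} series missing for years: {missing_y[:5]}")
    return pivot.loc[:, years]


def project(baseline: pd.DataFrame, spec: ScenarioSpec, fits: dict[str, HdiFit] | None = None) -> pd.DataFrame:
    """Project global agricultural emissions from base year to horizon.

    ``baseline`` has one row per country with base-year per-capita inputs:
    columns country, pc, pa, feed_kcal, ec, ea, oi_ratio and (for B/C)
    hdi_base. Countries with an incomplete input row are dropped with a log
    message; countries without an HDI series fall back to Scenario-A behavior.

    Returns one row per year: non-CO2 emissions from livestock and crop,
    fossil CO2 and their total (Gt CO2eq/yr), plus global food demand
    (kcal/yr) and fossil energy use (EJ/yr). The total is the exact sum of
    the three components every year.
    """
    need = ["country", "pc", "pa", "feed_kcal", "ec", "ea", "oi_ratio"]
    base = baseline.copy()
    complete = base[need].notna().all(axis=1) & (base["oi_ratio"] > 0)
    if (~complete).any():
        logger.info(
            "dropping %d countries with incomplete base-year inputs", (~complete).sum()
        )
        base = base[complete]
    if base.empty:
        raise ScenarioError("no countries with complete base-year inputs")
    countries = list(base["country"])
    years = list(range(spec.base_year, spec.horizon_year + 1))
    pop = _series_matrix(spec.population, "population", countries, years)

    dyn = spec.kind in ("B", "C")
    if dyn:
        for comp in ("total", "animal_products"):
            if fits is None or comp not in fits:
                raise ScenarioError(f"Scenario {spec.kind} needs an HDI fit for {comp!r}")
        hdi_pivot = spec.hdi.pivot(index="country", columns="year", values="hdi")
        have_hdi = [
            c
            for c in countries
            if c in hdi_pivot.index and not hdi_pivot.loc[c, [y for y in years if y in hdi_pivot.columns]].isna().any()
            and all(y in hdi_pivot.columns for y in years)
        ]
        fallback = sorted(set(countries) - set(have_hdi))
        if fallback:
            logger.info(
                "%d countries lack full HDI series; using Scenario-A behavior: %s",
                len(fallback), fallback[:5],
            )
    else:
        have_hdi = []

    base = base.set_index("country")
    pc0 = base["pc"].to_numpy(float)
    pa0 = base["pa"].to_numpy(float)
    feed0 = base["feed_kcal"].to_numpy(float)
    if spec.kind == "C":
        ec = np.full(len(countries), spec.policy.ec)
        ea = np.full(len(countries), spec.policy.ea)
        oi = np.full(len(countries), spec.policy.oi_ratio)
    else:
        ec = base["ec"].to_numpy(float)
        ea = base["ea"].to_numpy(float)
        oi = base["oi_ratio"].to_numpy(float)

    dyn_mask = np.array([c in have_hdi for c in countries]) if dyn else np.zeros(len(countries), bool)
    if dyn:
        hdi0 = np.array(
            [
                float(hdi_pivot.loc[c, spec.base_year]) if m else np.nan
                for c, m in zip(countries, dyn_mask)
            ]
        )
        ft, fa = fits["total"], fits["animal_products"]

    rows = []
    for year in years:
        pc_t, pa_t, feed_t = pc0.copy(), pa0.copy(), feed0.copy()
        total_t = pc0 + pa0
        if dyn and dyn_mask.any():
            h = np.array(
                [
                    float(hdi_pivot.loc[c, year]) if m else np.nan
                    for c, m in zip(countries, dyn_mask)
                ]
            )
            ratio_tot = np.exp(ft.slope * (h - hdi0))
            ratio_an = np.exp(fa.slope * (h - hdi0))
            tt = (pc0 + pa0) * ratio_tot
            # cap growth, but never cut a base-year diet already above the cap
            tt = np.minimum(tt, np.maximum(spec.cap, pc0 + pa0))
            aa = np.minimum(pa0 * ratio_an, tt)
            ff = np.where(pa0 > 0, feed0 * aa / np.where(pa0 > 0, pa0, 1.0), feed0)
            total_t = np.where(dyn_mask, tt, total_t)
            pa_t = np.where(dyn_mask, aa, pa_t)
            pc_t = total_t - pa_t
            feed_t = np.where(dyn_mask, ff, feed_t)

        ec_emis = pc_t * ec / 1000.0
        ea_emis = (pa_t * ea + feed_t * ec) / 1000.0
        fe = (pc_t + feed_t) / oi
        fossil = fe * spec.e_d / 1000.0
        p = pop[year].to_numpy(float)
        rows.append(
            dict(
                year=year,
                nonco2_crop=global_aggregate(ec_emis, p),
                nonco2_livestock=global_aggregate(ea_emis, p),
                fossil_co2=global_aggregate(fossil, p),
                food_demand_kcal=float(np.sum(total_t * p) * 365.0),
                fossil_energy_ej=float(np.sum(fe * p) * 365.0 * J_PER_KCAL / 1e18),
            )
        )
    out = pd.DataFrame(rows)
    out["total"] = out["nonco2_crop"] + out["nonco2_livestock"] + out["fossil_co2"]
    return out


def project_series_spec(
    food: pd.DataFrame,
    impacts: pd.DataFrame,
    labels: pd.DataFrame,
    hdi: pd.DataFrame,
    population: pd.DataFrame,
    hdi_proj: pd.DataFrame | None,
    kind: str,
    base_year: int,
    horizon_year: int = 2050,
) -> pd.DataFrame:
    """Convenience wrapper: build baseline, fits and policy from the input
    tables, then run :func:`project` for one scenario."""
    from .emissions import build_pattern_table

    fits = fit_components(labels, food, hdi) if kind in ("B", "C") else None
    baseline = country_baseline(food, impacts, base_year, hdi)
    policy = None
    if kind == "C":
        table = build_pattern_table(labels, food, impacts)
        ok = table.dropna(subset=["ec", "ea", "oi_ratio"])
        vh = ok[(ok["pc"] + ok["pa"]) >= 2800]["pattern"].tolist()
        policy = best_practice_policy(ok, vh or ok["pattern"].tolist())
    spec = ScenarioSpec(
        kind=kind,
        base_year=base_year,
        horizon_year=horizon_year,
        population=population,
        hdi=hdi_proj,
        policy=policy,
    )
    return project(baseline, spec, fits)


def country_baseline(
    food: pd.DataFrame,
    impacts: pd.DataFrame,
    base_year: int,
    hdi: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-country base-year inputs for :func:`project`."""
    from .emissions import country_intensities

    ci = country_intensities(food, impacts)
    base = ci[ci["year"] == base_year].drop(columns="year").reset_index(drop=True)
    if base.empty:
        raise ScenarioError(f"no records at base year {base_year}")
    if hdi is not None:
        h = hdi[hdi["year"] == base_year][["country", "hdi"]].rename(
            columns={"hdi": "hdi_base"}
        )
        base = base.merge(h, on="country", how="left")
    return base
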