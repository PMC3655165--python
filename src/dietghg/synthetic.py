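"""Synthetic country-year worlds with planted dietary archetypes.

The generator emulates the statistical shape of global food-balance data:
~50–200 countries observed yearly over ~47 years, each country-year described
by 11 food-group calorie supplies plus a total (kcal/cap/day), with

* 16 planted dietary archetypes spanning low to very-high calorie diets,
  anchored to the published per-pattern totals and compositions;
* a monotonically rising Human Development Index per country, with total
  calorie supply tied to HDI through an exponential (log-linear) law;
* Markov archetype trajectories that drift toward higher-calorie archetypes
  as HDI rises (the nutrition transition);
* consistent impact tables (energy output/input ratio, non-CO2 emission
  intensities, feed) drawn around per-archetype means.

Every country draws from its own random substream derived from one global
seed, so adding countries does not perturb existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FOOD_COLUMNS, FOOD_GROUPS

#: Per-archetype anchor values: total kcal/cap/day (crop + animal consumption),
#: feed use, non-CO2 emission intensities (g CO2eq/kcal) and energy O/I ratio,
#: mirroring the reference per-pattern impact table. Archetype 9's impact
#: fields are unavailable in the reference data (None here).
_ARCHETYPE_ANCHORS: list[tuple[int, float, float | None, float | None, float | None]] = [
    # id, total, feed, ec, ea, R
    (1, 1873, 268, 0.82, 12.48, 14.1),
    (2, 1999, 297, 0.42, 6.58, 26.2),
    (3, 2018, 278, 1.81, 4.30, 26.6),
    (4, 2138, 408, 0.64, 4.75, 7.9),
    (5, 2158, 511, 0.50, 3.25, 3.6),
    (6, 2172, 820, 1.07, 3.83, 5.0),
    (7, 2211, 445, 0.57, 13.06, 8.1),
    (8, 2266, 665, 0.44, 5.59, 20.3),
    (9, 2535, 138, None, None, None),
    (10, 2575, 1061, 0.37, 2.37, 2.1),
    (11, 2705, 1364, 0.91, 4.25, 2.3),
    (12, 2892, 2681, 0.32, 2.02, 2.2),
    (13, 3055, 1762, 0.52, 1.96, 2.5),
    (14, 3110, 3662, 0.51, 1.84, 1.7),
    (15, 3300, 5037, 0.32, 1.70, 2.1),
    (16, 3429, 4701, 0.31, 1.44, 2.1),
]
#: Composition fractions (share of total kcal) for the 11 food groups, one row
#: per archetype, designed along three latent axes — calorie level, staple type
#: (cereal vs roots/mixed) and animal/alcohol richness — and matching the
#: qualitative descriptions of the observed global patterns (e.g. #1 cereal-
#: dominated low-calorie, #4 rice-based, #9 island fruit/oilcrop, #14 meat-rich,
#: #16 Mediterranean). Row sums < 1; the remainder is "Others".
_ARCHETYPE_FRACTIONS: dict[int, dict[str, float]] = {
    1: dict(animal_products=0.078, cereals=0.55, pulses=0.05, starchy_roots=0.12,
            oilcrops=0.02, vegetable_oils=0.03, vegetables=0.02, fruits=0.03,
            sugar_sweeteners=0.03, sugarcrops=0.005, alcoholic_beverages=0.01),
    2: dict(animal_products=0.036, cereals=0.26, pulses=0.06, starchy_roots=0.46,
            oilcrops=0.03, vegetable_oils=0.03, vegetables=0.02, fruits=0.05,
            sugar_sweeteners=0.02, sugarcrops=0.005, alcoholic_beverages=0.01),
    3: dict(animal_products=0.056, cereals=0.35, pulses=0.08, starchy_roots=0.32,
            oilcrops=0.02, vegetable_oils=0.02, vegetables=0.02, fruits=0.04,
            sugar_sweeteners=0.02, sugarcrops=0.005, alcoholic_beverages=0.005),
    4: dict(animal_products=0.075, cereals=0.72, pulses=0.03, starchy_roots=0.03,
            oilcrops=0.01, vegetable_oils=0.02, vegetables=0.02, fruits=0.02,
            sugar_sweeteners=0.03, sugarcrops=0.002, alcoholic_beverages=0.002),
    5: dict(animal_products=0.127, cereals=0.50, pulses=0.09, starchy_roots=0.03,
            oilcrops=0.02, vegetable_oils=0.04, vegetables=0.04, fruits=0.04,
            sugar_sweeteners=0.08, sugarcrops=0.005, alcoholic_beverages=0.005),
    6: dict(animal_products=0.181, cereals=0.30, pulses=0.04, starchy_roots=0.25,
            oilcrops=0.02, vegetable_oils=0.03, vegetables=0.03, fruits=0.05,
            sugar_sweeteners=0.04, sugarcrops=0.005, alcoholic_beverages=0.02),
    7: dict(animal_products=0.060, cereals=0.62, pulses=0.02, starchy_roots=0.03,
            oilcrops=0.05, vegetable_oils=0.03, vegetables=0.02, fruits=0.02,
            sugar_sweeteners=0.05, sugarcrops=0.002, alcoholic_beverages=0.002),
    8: dict(animal_products=0.105, cereals=0.40, pulses=0.05, starchy_roots=0.12,
            oilcrops=0.03, vegetable_oils=0.05, vegetables=0.03, fruits=0.07,
            sugar_sweeteners=0.06, sugarcrops=0.01, alcoholic_beverages=0.02),
    9: dict(animal_products=0.152, cereals=0.30, pulses=0.02, starchy_roots=0.10,
            oilcrops=0.10, vegetable_oils=0.04, vegetables=0.02, fruits=0.12,
            sugar_sweeteners=0.06, sugarcrops=0.01, alcoholic_beverages=0.02),
    10: dict(animal_products=0.106, cereals=0.55, pulses=0.04, starchy_roots=0.04,
             oilcrops=0.02, vegetable_oils=0.05, vegetables=0.04, fruits=0.04,
             sugar_sweeteners=0.05, sugarcrops=0.005, alcoholic_beverages=0.01),
    11: dict(animal_products=0.172, cereals=0.40, pulses=0.05, starchy_roots=0.04,
             oilcrops=0.02, vegetable_oils=0.06, vegetables=0.04, fruits=0.06,
             sugar_sweeteners=0.08, sugarcrops=0.01, alcoholic_beverages=0.02),
    12: dict(animal_products=0.214, cereals=0.40, pulses=0.02, starchy_roots=0.07,
             oilcrops=0.01, vegetable_oils=0.05, vegetables=0.04, fruits=0.04,
             sugar_sweeteners=0.06, sugarcrops=0.005, alcoholic_beverages=0.04),
    13: dict(animal_products=0.145, cereals=0.52, pulses=0.02, starchy_roots=0.03,
             oilcrops=0.02, vegetable_oils=0.06, vegetables=0.05, fruits=0.05,
             sugar_sweeteners=0.06, sugarcrops=0.005, alcoholic_beverages=0.003),
    14: dict(animal_products=0.350, cereals=0.28, pulses=0.01, starchy_roots=0.08,
             oilcrops=0.01, vegetable_oils=0.04, vegetables=0.03, fruits=0.03,
             sugar_sweeteners=0.08, sugarcrops=0.002, alcoholic_beverages=0.06),
    15: dict(animal_products=0.319, cereals=0.18, pulses=0.005, starchy_roots=0.03,
             oilcrops=0.01, vegetable_oils=0.07, vegetables=0.03, fruits=0.05,
             sugar_sweeteners=0.13, sugarcrops=0.005, alcoholic_beverages=0.08),
    16: dict(animal_products=0.239, cereals=0.28, pulses=0.02, starchy_roots=0.04,
             oilcrops=0.02, vegetable_oils=0.10, vegetables=0.06, fruits=0.08,
             sugar_sweeteners=0.08, sugarcrops=0.005, alcoholic_beverages=0.04),
}


class ConfigError(ValueError):
    """Invalid world configuration; raised before any sampling."""


@dataclass(frozen=True)
class Archetype:
    """A planted dietary archetype: composition shares and total-calorie scale."""

    id: int
    composition_frac: dict[str, float]
    total_kcal_mean: float
    total_kcal_sd: float = 0.0

    def __post_init__(self):
        fr = np.array([self.composition_frac[g] for g in FOOD_GROUPS])
        if (fr < 0).any() or (fr > 1).any() or fr.sum() > 1 + 1e-9:
            raise ConfigError(f"archetype {self.id}: invalid composition fractions")
        if self.total_kcal_mean <= 0:
            raise ConfigError(f"archetype {self.id}: total_kcal_mean must be > 0")


@dataclass(frozen=True)
class ArchetypeImpact:
    """Per-archetype impact means; None marks a variable unavailable."""

    oi_ratio: float | None
    ec: float | None
    ea: float | None
    feed_kcal: float


@dataclass
class WorldConfig:
    """Configuration of a synthetic world.

    ``hdi_link = (a, b)`` defines the generative law for total calories,
    ``ln total = a + b * HDI`` (plus lognormal noise ``total_sd_ln``); each
    archetype's HDI "center" is the HDI at which the law yields the archetype's
    mean total, so archetype occupancy tracks development level.
    """

    n_countries: int = 50
    year_range: tuple[int, int] = (1961, 2007)
    archetypes: tuple[Archetype, ...] = ()
    concentration: float | None = 300.0
    hdi_link: tuple[float, float] = (7.26, 1.0)
    total_sd_ln: float = 0.03
    transition_rate: float = 0.25
    impact_sd_ln: float = 0.05
    impact_params: dict[int, ArchetypeImpact] = field(default_factory=dict)
    hdi_ceiling: float = 0.97
    seed: int = 0

    def __post_init__(self):
        if not self.archetypes:
            self.archetypes = default_archetypes()
        if not self.impact_params:
            self.impact_params = default_impact_params()
        if self.n_countries < 1:
            raise ConfigError("n_countries must be >= 1")
        if self.year_range[1] < self.year_range[0]:
            raise ConfigError("year_range must be increasing")
        if not 0.0 <= self.transition_rate <= 1.0:
            raise ConfigError("transition_rate must lie in [0, 1]")
        if self.concentration is not None and self.concentration <= 0:
            raise ConfigError("concentration must be positive or None (no noise)")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.hdi_link[1] <= 0:
            raise ConfigError("HDI slope must be positive")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)

    def archetype_centers(self) -> dict[int, float]:
        """HDI at which the total-calorie law equals each archetype's mean total."""
        a, b = self.hdi_link
        return {
            arch.id: (math.log(arch.total_kcal_mean) - a) / b for arch in self.archetypes
        }


def default_archetypes() -> tuple[Archetype, ...]:
    """The 16 default archetypes, spanning the four calorie classes."""
    out = []
    for (aid, total, _feed, _ec, _ea, _r) in _ARCHETYPE_ANCHORS:
        out.append(
            Archetype(
                id=aid,
                composition_frac=dict(_ARCHETYPE_FRACTIONS[aid]),
                total_kcal_mean=float(total),
                total_kcal_sd=0.03 * total,
            )
        )
    return tuple(out)


def default_impact_params() -> dict[int, ArchetypeImpact]:
    return {
        aid: ArchetypeImpact(oi_ratio=r, ec=ec, ea=ea, feed_kcal=float(feed))
        for (aid, _total, feed, ec, ea, r) in _ARCHETYPE_ANCHORS
    }


@dataclass
class World:
    """A simulated world: the four input tables plus the planted ground truth."""

    config: WorldConfig
    food: pd.DataFrame
    impacts: pd.DataFrame
    hdi: pd.DataFrame
    population: pd.DataFrame
    labels: pd.DataFrame  # country, year, archetype
    country_params: pd.DataFrame  # per-country trajectory parameters
    transition_log: list[tuple[str, int, int, int]] = field(default_factory=list)


def _hdi_path(h0: float, rate: float, n_years: int, ceiling: float) -> np.ndarray:
    """Logistic approach toward the ceiling; strictly increasing."""
    h = np.empty(n_years)
    h[0] = h0
    for t in range(1, n_years):
        h[t] = h[t - 1] + rate * h[t - 1] * (1.0 - h[t - 1] / ceiling)
    return h


def simulate_world(config: WorldConfig) -> World:
    """Simulate a world under ``config``; identical config → identical output."""
    archetypes = {a.id: a for a in config.archetypes}
    order = [a.id for a in sorted(config.archetypes, key=lambda a: a.total_kcal_mean)]
    rank = {aid: i for i, aid in enumerate(order)}
    centers = config.archetype_centers()
    a_link, b_link = config.hdi_link
    years = config.years
    n_years = len(years)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_countries)

    food_rows, impact_rows, hdi_rows, pop_rows, label_rows = [], [], [], [], []
    cp_rows = []
    transition_log: list[tuple[str, int, int, int]] = []

    for ci in range(config.n_countries):
        rng = np.random.default_rng(children[ci])
        country = f"C{ci:03d}"
        h0 = rng.uniform(0.20, 0.90)
        # relative logistic growth 0.5–4%/yr: some countries nearly static over
        # the window, a few undergo a full nutrition transition
        hrate = rng.uniform(0.005, 0.04)
        hdi = _hdi_path(h0, hrate, n_years, config.hdi_ceiling)
        pop0 = 10 ** rng.uniform(6.0, 8.0)
        prate = rng.uniform(0.005, 0.025)
        pop = pop0 * np.exp(prate * np.arange(n_years))
        cp_rows.append(
            dict(country=country, hdi0=h0, hdi_rate=hrate, pop0=pop0, pop_rate=prate)
        )

        def nearest(h: float) -> int:
            return min(centers, key=lambda aid: abs(centers[aid] - h))

        z = nearest(hdi[0])
        for t, year in enumerate(years):
            if t > 0:
                target = nearest(hdi[t])
                if target != z and rng.random() < config.transition_rate:
                    step = 1 if rank[target] > rank[z] else -1
                    z_new = order[rank[z] + step]
                    transition_log.append((country, int(year), z, z_new))
                    z = z_new
            arch = archetypes[z]

            eps = rng.normal(0.0, config.total_sd_ln) if config.total_sd_ln > 0 else 0.0
            total = math.exp(a_link + b_link * hdi[t] + eps)

            frac = np.array([arch.composition_frac[g] for g in FOOD_GROUPS])
            others = 1.0 - frac.sum()
            if config.concentration is None or not np.isfinite(config.concentration):
                noisy = frac
            else:
                alpha = np.append(frac, others) * config.concentration
                draw = rng.dirichlet(np.maximum(alpha, 1e-6))
                noisy = draw[:-1]
            groups = noisy * total

            row = dict(country=country, year=int(year))
            row.update({g: groups[i] for i, g in enumerate(FOOD_GROUPS)})
            row["total_kcal"] = total
            food_rows.append(row)
            label_rows.append(dict(country=country, year=int(year), archetype=z))
            hdi_rows.append(dict(country=country, year=int(year), hdi=hdi[t]))
            pop_rows.append(dict(country=country, year=int(year), population=pop[t]))

            imp = config.impact_params[z]
            sd = config.impact_sd_ln

            def ln_noise() -> float:
                return math.exp(rng.normal(0.0, sd)) if sd > 0 else 1.0

            pa = groups[FOOD_GROUPS.index("animal_products")]
            pc = total - pa
            crop_prod = pc * ln_noise()
            animal_prod = max(pa, 1.0) * ln_noise()
            irow = dict(
                country=country,
                year=int(year),
                oi_ratio=imp.oi_ratio * ln_noise() if imp.oi_ratio else np.nan,
                crop_nonco2_g=imp.ec * crop_prod * ln_noise() if imp.ec else np.nan,
                livestock_nonco2_g=imp.ea * animal_prod * ln_noise() if imp.ea else np.nan,
                crop_prod_kcal=crop_prod,
                animal_prod_kcal=animal_prod,
                feed_kcal=imp.feed_kcal * ln_noise(),
                population=pop[t],
            )
            impact_rows.append(irow)

    food = pd.DataFrame(food_rows, columns=list(FOOD_COLUMNS))
    return World(
        config=config,
        food=food,
        impacts=pd.DataFrame(impact_rows),
        hdi=pd.DataFrame(hdi_rows),
        population=pd.DataFrame(pop_rows),
        labels=pd.DataFrame(label_rows),
        country_params=pd.DataFrame(cp_rows),
        transition_log=transition_log,
    )


def planted_truth(world: World) -> dict[tuple[str, int], int]:
    """Exact generating labels, keyed by (country, year)."""
    return {
        (row.country, int(row.year)): int(row.archetype)
        for row in world.labels.itertuples(index=False)
    }


def project_series(world: World, horizon_year: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministically extend each country's HDI and population to ``horizon_year``.

    Continues the logistic HDI trajectory and the exponential population growth
    with each country's own generating parameters; returns (hdi, population)
    tables covering base year (last observed) through the horizon.
    """
    base_year = int(world.config.year_range[1])
    if horizon_year < base_year:
        raise ConfigError("horizon before the last observed year")
    n_obs = len(world.config.years)
    n_ext = horizon_year - world.config.year_range[0] + 1
    hdi_rows, pop_rows = [], []
    for cp in world.country_params.itertuples(index=False):
        hdi = _hdi_path(cp.hdi0, cp.hdi_rate, n_ext, world.config.hdi_ceiling)
        pop = cp.pop0 * np.exp(cp.pop_rate * np.arange(n_ext))
        for t in range(n_obs - 1, n_ext):
            year = world.config.year_range[0] + t
            hdi_rows.append(dict(country=cp.country, year=year, hdi=hdi[t]))
            pop_rows.append(dict(country=cp.country, year=year, population=pop[t]))
    return pd.DataFrame(hdi_rows), pd.DataFrame(pop_rows)
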