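"""From map labels to dietary patterns: summaries, calorie classes, transitions.

Pattern ids 1..N are assigned by ascending mean total calories of the trained
map's nodes, so the numbering is stable across retrainings (raw SOM node
order is arbitrary) and pattern #1 is always the lowest-calorie diet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .som import SOMMap, bmu_labels
from .tables import FOOD_GROUPS

CALORIE_CLASSES = ("low", "moderate", "high", "very_high")

#: Lower-inclusive class boundaries in kcal/cap/day:
#: low [0, 2100), moderate [2100, 2400), high [2400, 2800), very_high [2800, ∞).
CLASS_THRESHOLDS = (2100.0, 2400.0, 2800.0)


def calorie_class(total_kcal: float) -> str:
    """Classify a total calorie supply into the four diet classes."""
    if total_kcal < 0:
        raise ValueError(f"total calories must be >= 0, got {total_kcal}")
    for name, upper in zip(CALORIE_CLASSES[:-1], CLASS_THRESHOLDS):
        if total_kcal < upper:
            return name
    return "very_high"


def pattern_order(som: SOMMap) -> np.ndarray:
    """node index -> pattern id (1-based), ordered by node mean total calories.

    The total-calorie variable is assumed to be the last input column.
    """
    totals = som.unscale_weights()[:, -1]
    order = np.argsort(totals, kind="stable")
    ids = np.empty(som.n_nodes, dtype=int)
    ids[order] = np.arange(1, som.n_nodes + 1)
    return ids


def assign_patterns(som: SOMMap, food: pd.DataFrame) -> pd.DataFrame:
    """Label every food-table row with its calorie-ordered pattern id."""
    data = food[list(FOOD_GROUPS) + ["total_kcal"]].to_numpy(dtype=float)
    nodes = bmu_labels(som, data)
    ids = pattern_order(som)
    return pd.DataFrame(
        dict(country=food["country"], year=food["year"], pattern=ids[nodes])
    )


@dataclass
class PatternSummary:
    pattern_id: int
    n_members: int
    mean_composition: dict[str, float] = field(default_factory=dict)  # incl. "others"
    mean_total_kcal: float | None = None
    calorie_class: str | None = None


def summarize_patterns(
    labels: pd.DataFrame,
    food: pd.DataFrame,
    population: pd.DataFrame | None = None,
    n_patterns: int | None = None,
) -> tuple[list[PatternSummary], pd.DataFrame | None]:
    """Per-pattern composition means; optionally people per pattern per year.

    Every labeled (country, year) must have a food record. Returns the
    summaries and, when a population table is supplied, a (year × pattern)
    table of total population living on each pattern.
    """
    merged = labels.merge(food, on=["country", "year"], how="left", indicator=True)
    missing = merged["_merge"] != "both"
    if missing.any():
        keys = merged.loc[missing, ["country", "year"]].itertuples(index=False)
        raise ValueError(
            "labels without food records: "
            + ", ".join(f"({c}, {y})" for c, y in list(keys)[:5])
        )
    merged = merged.drop(columns="_merge")
    merged["others"] = merged["total_kcal"] - merged[list(FOOD_GROUPS)].sum(axis=1)

    ids = range(1, (n_patterns or int(labels["pattern"].max())) + 1)
    summaries = []
    for z in ids:
        sub = merged[merged["pattern"] == z]
        if len(sub) == 0:
            summaries.append(PatternSummary(pattern_id=z, n_members=0))
            continue
        comp = {g: float(sub[g].mean()) for g in FOOD_GROUPS}
        comp["others"] = float(sub["others"].mean())
        total = float(sub["total_kcal"].mean())
        summaries.append(
            PatternSummary(
                pattern_id=z,
                n_members=len(sub),
                mean_composition=comp,
                mean_total_kcal=total,
                calorie_class=calorie_class(total),
            )
        )

    people = None
    if population is not None:
        m = labels.merge(population, on=["country", "year"], how="left")
        people = (
            m.pivot_table(
                index="year", columns="pattern", values="population", aggfunc="sum"
            )
            .fillna(0.0)
            .sort_index()
        )
    return summaries, people


def transition_matrix(labels: pd.DataFrame, n_patterns: int = 16) -> np.ndarray:
    """Count year-to-year pattern changes per country.

    Cell (i−1, j−1) counts countries moving from pattern i in year y to
    pattern j in year y+1, over all pairs of consecutive calendar years both
    present for that country; gaps contribute nothing. The diagonal counts
    unchanged memberships.
    """
    counts = np.zeros((n_patterns, n_patterns), dtype=int)
    for _, sub in labels.groupby("country", sort=False):
        s = sub.sort_values("year")
        years = s["year"].to_numpy()
        pats = s["pattern"].to_numpy()
        consec = np.diff(years) == 1
        for a, b in zip(pats[:-1][consec], pats[1:][consec]):
            counts[a - 1, b - 1] += 1
    return counts


def transition_graph(matrix: np.ndarray, min_count: int = 10) -> list[tuple[int, int, int]]:
    """Off-diagonal transitions occurring at least ``min_count`` times.

    Returns directed edges (src_pattern, dst_pattern, count), 1-based ids;
    the diagonal (no change) is never emitted.
    """
    matrix = np.asarray(matrix)
    edges = []
    n = matrix.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and matrix[i, j] >= min_count:
                edges.append((i + 1, j + 1, int(matrix[i, j])))
    return edges


def summaries_frame(summaries: list[PatternSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dict(
            pattern=s.pattern_id,
            n_members=s.n_members,
            mean_total_kcal=s.mean_total_kcal,
            calorie_class=s.calorie_class,
        )
        row.update({g: s.mean_composition.get(g) for g in FOOD_GROUPS})
        row["others"] = s.mean_composition.get("others")
        rows.append(row)
    return pd.DataFrame(rows)
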