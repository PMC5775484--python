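"""Reference data: the tracked ingredient foods, their B12 contents and costs.

Twelve ingredient foods are tracked in recipe searches. Eleven of them carry
vitamin B12 (contents in mcg per 100 g, from the NIH Office of Dietary
Supplements); tomatoes are the twelfth, a negligible-B12 negative control
with content 0.
"""

from __future__ import annotations

import pandas as pd

# (food, mcg B12 per 100 g), descending content.
_B12_CONTENTS: list[tuple[str, float]] = [
    ("shellfish", 98.9),
    ("mackerel", 19.0),
    ("beef", 6.0),
    ("trout", 3.8),
    ("salmon", 2.4),
    ("tuna", 1.6),
    ("milk", 0.9),
    ("turkey", 0.8),
    ("egg", 0.6),
    ("pork", 0.4),
    ("chicken", 0.3),
]

#: The 11 foods with appreciable B12 content, in canonical order.
B12_FOODS: tuple[str, ...] = tuple(name for name, _ in _B12_CONTENTS)

#: All 12 tracked ingredient foods (tomatoes last, content 0).
FOODS: tuple[str, ...] = B12_FOODS + ("tomatoes",)

# Approximate retail cost per serving in USD. The cost source used by the
# original validation is a government food-cost table; these stand-in values
# are of realistic relative magnitude. Only cost-weighted *fractions* enter
# any computation, so the absolute scale is irrelevant.
_UNIT_COSTS: dict[str, float] = {
    "shellfish": 5.50,
    "mackerel": 3.20,
    "beef": 3.80,
    "trout": 4.10,
    "salmon": 4.60,
    "tuna": 2.10,
    "milk": 0.60,
    "turkey": 2.40,
    "egg": 0.35,
    "pork": 2.90,
    "chicken": 1.90,
    "tomatoes": 0.80,
}

#: Mapping from the 12 foods onto the 6 expenditure-survey categories used
#: in the regional consumption validation.
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "beef": "beef",
    "pork": "pork",
    "chicken": "poultry",
    "turkey": "poultry",
    "shellfish": "fish_seafood",
    "mackerel": "fish_seafood",
    "trout": "fish_seafood",
    "salmon": "fish_seafood",
    "tuna": "fish_seafood",
    "egg": "eggs",
    "milk": "milk",
}

EXPENDITURE_CATEGORIES: tuple[str, ...] = (
    "beef",
    "pork",
    "poultry",
    "fish_seafood",
    "eggs",
    "milk",
)


def count_column(food: str) -> str:
    """Column name holding a user's recipe-search count for ``food``."""
    return f"count_{food}"


COUNT_COLUMNS: tuple[str, ...] = tuple(count_column(f) for f in FOODS)


def generate_food_reference(
    overrides: dict[str, float] | None = None,
    cost_overrides: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Build the food reference table (12 rows: food, b12 content, unit cost).

    Parameters
    ----------
    overrides
        Optional map ``food -> mcg/100 g`` replacing default B12 contents.
        Keys must name one of the 12 tracked foods.
    cost_overrides
        Optional map ``food -> USD/serving`` replacing default unit costs.

    Returns
    -------
    DataFrame with columns ``food``, ``b12_mcg_per_100g``, ``unit_cost``,
    indexed 0..11 in canonical food order (tomatoes last, content 0 by
    default).
    """
    contents = dict(_B12_CONTENTS)
    contents["tomatoes"] = 0.0
    for mapping, label in ((overrides, "overrides"), (cost_overrides, "cost_overrides")):
        if mapping:
            unknown = set(mapping) - set(FOODS)
            if unknown:
                raise ValueError(
                    f"unknown food name(s) in {label}: {sorted(unknown)}; "
                    f"known foods: {list(FOODS)}"
                )
    if overrides:
        contents.update(overrides)
    costs = dict(_UNIT_COSTS)
    if cost_overrides:
        costs.update(cost_overrides)
    return pd.DataFrame(
        {
            "food": list(FOODS),
            "b12_mcg_per_100g": [float(contents[f]) for f in FOODS],
            "unit_cost": [float(costs[f]) for f in FOODS],
        }
    )


def content_vector(foods: pd.DataFrame, food_names: tuple[str, ...] = FOODS):
    """B12 contents aligned to ``food_names`` as a float numpy array."""
    series = foods.set_index("food")["b12_mcg_per_100g"]
    missing = [f for f in food_names if f not in series.index]
    if missing:
        raise KeyError(f"food reference is missing: {missing}")
    return series.reindex(list(food_names)).to_numpy(dtype=float)
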