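"""Per-user estimated B12 consumption and the consumption-side analyses.

The consumption score of a user is the dot product of the foods' B12
contents (mcg/100 g) with the user's recipe-search counts for each food.
Around it sit three validations: a regional cost-weighted comparison with
expenditure-survey fractions, awareness-group consumption contrasts
(rank-sum tested), and the deficiency x supplement query contingency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import DEFAULT_CATEGORY_MAP, FOODS, count_column

logger = logging.getLogger(__name__)


def estimate_b12(profiles: pd.DataFrame, foods: pd.DataFrame) -> pd.Series:
    """Estimated B12 consumption score per user (mcg).

    score_u = sum_i content_i * count_{u,i} over the tracked foods present
    in ``foods`` (tomatoes contribute 0 by default content). Raises KeyError
    naming any count column missing from ``profiles``.
    """
    contents = foods.set_index("food")["b12_mcg_per_100g"]
    cols, values = [], []
    for food in foods["food"]:
        col = count_column(food)
        if col not in profiles.columns:
            raise KeyError(f"profile table is missing count column {col!r}")
        cols.append(col)
        values.append(contents[food])
    scores = profiles[cols].to_numpy(dtype=float) @ np.asarray(values)
    return pd.Series(scores, index=profiles.index, name="b12_score")


def ranksum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when the smaller sample has <= 10 observations
    and there are no ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    exact = min(len(a), len(b)) <= 10 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def relative_difference(mean_base: float, mean_other: float) -> float:
    """Percent difference of ``mean_other`` vs ``mean_base`` (base denominator)."""
    return 100.0 * (mean_other - mean_base) / mean_base


@dataclass
class GroupContrast:
    """Consumption contrast between a flagged group and its complement.

    ``relative_difference`` is in percent with the flagged group's mean as
    denominator; ``relative_difference_other_base`` uses the unflagged mean.
    """

    flag_name: str
    mean_flagged: float
    mean_unflagged: float
    relative_difference: float
    relative_difference_other_base: float
    ranksum_p: float
    n_flagged: int
    n_unflagged: int


def contrast_by_flag(
    scores: pd.Series, flags: pd.Series, flag_name: str = "flag"
) -> GroupContrast:
    """Compare mean consumption of flag=True users against flag=False users."""
    flags = flags.astype(bool).to_numpy()
    a = scores.to_numpy(dtype=float)[flags]
    b = scores.to_numpy(dtype=float)[~flags]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"contrast on {flag_name!r}: one group is empty")
    ma, mb = float(a.mean()), float(b.mean())
    return GroupContrast(
        flag_name=flag_name,
        mean_flagged=ma,
        mean_unflagged=mb,
        relative_difference=relative_difference(ma, mb),
        relative_difference_other_base=relative_difference(mb, ma),
        ranksum_p=ranksum_test(a, b),
        n_flagged=len(a),
        n_unflagged=len(b),
    )


@dataclass
class ContingencyResult:
    """2x2 of asked-deficiency x asked-supplement with the rate ratio.

    ``a``..``d`` follow the layout (deficiency & supplement, deficiency &
    not, no-deficiency & supplement, no-deficiency & not); the rate ratio is
    (a/(a+b)) / (c/(c+d)), reported as inf with ``ratio_infinite`` set when
    c = 0.
    """

    a: int
    b: int
    c: int
    d: int
    p_supplement_given_deficiency: float
    p_supplement_given_no_deficiency: float
    rate_ratio: float
    ratio_infinite: bool

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int) -> "ContingencyResult":
        if a + b == 0:
            raise ValueError("no deficiency-askers in the sample")
        p1 = a / (a + b)
        p0 = c / (c + d) if (c + d) > 0 else 0.0
        infinite = p0 == 0.0 and p1 > 0.0
        ratio = float("inf") if infinite else (0.0 if p1 == 0.0 else p1 / p0)
        return cls(a, b, c, d, p1, p0, ratio, infinite)


def supplement_contrast(profiles: pd.DataFrame) -> ContingencyResult:
    """Build the deficiency x supplement contingency from user profiles."""
    dfc = profiles["asked_deficiency"].astype(bool)
    sup = profiles["asked_supplement"].astype(bool)
    a = int((dfc & sup).sum())
    b = int((dfc & ~sup).sum())
    c = int((~dfc & sup).sum())
    d = int((~dfc & ~sup).sum())
    return ContingencyResult.from_counts(a, b, c, d)


def regional_query_fractions(
    profiles: pd.DataFrame,
    foods: pd.DataFrame,
    category_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Cost-weighted per-region food-category fractions of recipe searches.

    fraction_{r,c} = sum_{i in c} cost_i * count_{r,i} / sum over all
    categories, where count_{r,i} sums food-i search counts of users in
    region r. Regions with zero recipe queries are excluded with a log
    message. Returns (region, category, fraction).
    """
    cmap = category_map or DEFAULT_CATEGORY_MAP
    cost = foods.set_index("food")["unit_cost"]
    categories = sorted(set(cmap.values()))
    out = []
    for region, sub in profiles.groupby("region"):
        totals = {
            cat: sum(
                float(sub[count_column(f)].sum()) * cost[f]
                for f, c in cmap.items()
                if c == cat
            )
            for cat in categories
        }
        denom = sum(totals.values())
        if denom == 0:
            logger.warning("region %r has no recipe queries; excluded", region)
            continue
        for cat in categories:
            out.append((region, cat, totals[cat] / denom))
    return pd.DataFrame(out, columns=["region", "category", "fraction"])


def validate_regional(
    profiles: pd.DataFrame,
    foods: pd.DataFrame,
    expenditure: pd.DataFrame,
    category_map: dict[str, str] | None = None,
) -> tuple[float, float, int]:
    """Pearson correlation between query-derived and survey spending fractions.

    Both tables are aligned on (region, category) cells; returns
    ``(r, p, n_cells)`` over the common cells (the study design is 4 regions
    x 6 categories = 24 cells).
    """
    ours = regional_query_fractions(profiles, foods, category_map)
    merged = ours.merge(
        expenditure, on=["region", "category"], suffixes=("_query", "_survey")
    )
    if len(merged) < 3:
        raise ValueError("fewer than 3 aligned region x category cells")
    r, p = stats.pearsonr(merged["fraction_query"], merged["fraction_survey"])
    return float(r), float(p), len(merged)
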