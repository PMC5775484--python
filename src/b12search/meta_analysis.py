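"""Relating CoB12 to drug popularity and indication breadth.

Drugs with many indications are asked about by many kinds of patients,
which can dilute the intake signal behind their CoB12, while drugs used
mostly for pain should concentrate it. This module computes Spearman
correlations of indication counts with term popularity and fits the
R2I-weighted rank-regression meta-model: CoB12 (rank-transformed) on the
ranks of asker counts, indication counts and pain-indication counts, with
all pairwise and the three-way interaction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

META_PREDICTORS = ("n_askers", "n_indications", "n_pain_indications")


def indication_correlations(
    results: pd.DataFrame, indications: pd.DataFrame
) -> dict:
    """Spearman correlation of indication counts with term popularity.

    Joins the term-model results with the indication table (terms without an
    indication record are excluded) and correlates ``n_indications`` and
    ``n_pain_indications`` with ``n_askers``. Raises when fewer than 3 drug
    terms survive the join.
    """
    merged = results.merge(indications, on="term")
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} terms with indication records (need >= 3)")
    rho_ind, p_ind = stats.spearmanr(merged["n_indications"], merged["n_askers"])
    rho_pain, p_pain = stats.spearmanr(merged["n_pain_indications"], merged["n_askers"])
    return {
        "rho_ind_vs_n": float(rho_ind),
        "p_ind_vs_n": float(p_ind),
        "rho_pain_vs_n": float(rho_pain),
        "p_pain_vs_n": float(p_pain),
        "n_terms": len(merged),
    }


def _centered_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks rescaled to [-1, 1] with mean 0."""
    n = len(x)
    r = stats.rankdata(x, method="average")
    if n == 1:
        return np.zeros(1)
    return (r - (n + 1) / 2.0) / ((n - 1) / 2.0)


@dataclass
class MetaModelResult:
    """Weighted rank-regression fit of CoB12 on popularity and indications."""

    r2: float
    slopes: dict[str, float]
    p_values: dict[str, float]
    n_terms: int
    weights_used: str = "r2i"
    dropped_terms: list[str] = field(default_factory=list)


def fit_meta_model(
    results: pd.DataFrame, indications: pd.DataFrame
) -> MetaModelResult:
    """Fit the R2I-weighted rank regression of CoB12 on drug covariates.

    The response (CoB12) and the three predictors (asker count, indication
    count, pain-indication count) are replaced by average ranks centered and
    scaled to [-1, 1]; the design holds the three main effects, all pairwise
    products and the three-way product. Weights are R2I values normalized to
    mean 1 (all-equal R2I reduces to unweighted rank regression). If the
    design is numerically collinear, interaction columns are dropped in
    fixed order (three-way first) with a log message.
    """
    merged = results.merge(indications, on="term")
    if len(merged) < 6:
        raise ValueError(f"only {len(merged)} drug terms after join (need >= 6)")
    merged = merged.dropna(subset=["cob12"])
    y = _centered_ranks(merged["cob12"].to_numpy())
    ranks = {p: _centered_ranks(merged[p].to_numpy()) for p in META_PREDICTORS}
    a, b, c = (ranks[p] for p in META_PREDICTORS)
    columns: dict[str, np.ndarray] = {
        "n_askers": a,
        "n_indications": b,
        "n_pain_indications": c,
        "n_askers:n_indications": a * b,
        "n_askers:n_pain_indications": a * c,
        "n_indications:n_pain_indications": b * c,
        "n_askers:n_indications:n_pain_indications": a * b * c,
    }
    weights = merged["r2i"].to_numpy(dtype=float)
    if weights.sum() <= 0:
        raise ValueError("R2I weights are all zero")
    weights = weights / weights.mean()

    drop_order = [
        "n_askers:n_indications:n_pain_indications",
        "n_indications:n_pain_indications",
        "n_askers:n_pain_indications",
        "n_askers:n_indications",
    ]
    dropped: list[str] = []
    while True:
        names = [k for k in columns if k not in dropped]
        design = np.column_stack([columns[k] for k in names])
        x = sm.add_constant(design, has_constant="add")
        if np.linalg.matrix_rank(x) == x.shape[1] or not any(
            d in names for d in drop_order
        ):
            break
        nxt = next(d for d in drop_order if d in names)
        dropped.append(nxt)
        logger.warning("collinear rank design; dropping %s", nxt)

    fit = sm.WLS(y, x, weights=weights).fit()
    slopes = dict(zip(names, fit.params[1:]))
    p_values = dict(zip(names, fit.pvalues[1:]))
    return MetaModelResult(
        r2=float(fit.rsquared),
        slopes={k: float(v) for k, v in slopes.items()},
        p_values={k: float(v) for k, v in p_values.items()},
        n_terms=len(merged),
        dropped_terms=dropped,
    )


# ---------------------------------------------------------------------------
# unified report
# ---------------------------------------------------------------------------

def build_report(
    consumption_contrasts: dict | None = None,
    contingency=None,
    regional: tuple | None = None,
    top_terms: pd.DataFrame | None = None,
    set_contrast: dict | None = None,
    correlations: dict | None = None,
    meta: MetaModelResult | None = None,
    config: dict | None = None,
) -> dict:
    """Assemble the stage outputs into one structured, serializable report.

    Missing stages are marked absent rather than failing, so a partial
    pipeline still yields a report. The report is deterministic given the
    inputs (dict insertion order is fixed).
    """
    report: dict = {"config": config or {}}

    def section(name, value, render):
        report[name] = {"present": value is not None}
        if value is not None:
            report[name].update(render(value))

    section(
        "consumption_contrasts",
        consumption_contrasts,
        lambda d: {
            name: {
                "mean_flagged": round(gc.mean_flagged, 4),
                "mean_unflagged": round(gc.mean_unflagged, 4),
                "relative_difference_pct": round(gc.relative_difference, 2),
                "ranksum_p": gc.ranksum_p,
                "n_flagged": gc.n_flagged,
                "n_unflagged": gc.n_unflagged,
            }
            for name, gc in d.items()
        },
    )
    section(
        "supplement_contingency",
        contingency,
        lambda ct: {
            "counts": [ct.a, ct.b, ct.c, ct.d],
            "pct_supplement_given_deficiency": round(
                100 * ct.p_supplement_given_deficiency, 2
            ),
            "pct_supplement_given_no_deficiency": round(
                100 * ct.p_supplement_given_no_deficiency, 2
            ),
            "rate_ratio": None if ct.ratio_infinite else round(ct.rate_ratio, 1),
            "ratio_infinite": ct.ratio_infinite,
        },
    )
    section(
        "regional_validation",
        regional,
        lambda t: {"pearson_r": round(t[0], 2), "p": t[1], "n_cells": t[2]},
    )
    section(
        "top_terms",
        top_terms,
        lambda df: {
            "table": [
                {
                    "term": row["term"],
                    "r2i": round(row["r2i"], 3),
                    "cob12": round(row["cob12"], 3),
                }
                for _, row in df.iterrows()
            ]
        },
    )
    section("set_contrast", set_contrast, lambda d: {k: d[k] for k in sorted(d)})
    section("correlations", correlations, lambda d: {k: d[k] for k in sorted(d)})
    section(
        "meta_model",
        meta,
        lambda m: {
            "r2": round(m.r2, 2),
            "slopes": {k: round(v, 2) for k, v in m.slopes.items()},
            "p_values": m.p_values,
            "n_terms": m.n_terms,
            "weights_used": m.weights_used,
            "dropped_terms": m.dropped_terms,
        },
    )
    return report


def render_report(report: dict) -> str:
    """Render a report dict as deterministic, human-readable text."""
    return json.dumps(report, indent=2, sort_keys=False, default=str)
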