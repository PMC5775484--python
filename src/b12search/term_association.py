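"""Per-term individual-level models linking food searches to symptom queries.

For each medical term a linear probability model is fitted by ordinary
least squares: the 0/1 indicator of whether a user asked about the term is
regressed on the user's recipe-search counts for each B12 food (plus an
intercept). Its coefficient of determination is the term's R2I, and the
Pearson correlation between its per-food coefficients and the foods' B12
contents is the term's CoB12 - negative CoB12 means users searching for
B12-rich foods ask about the term less. Target terms (hypothesized to be
intake-related) are contrasted against control terms on both statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .consumption import ranksum_test
from .reference import B12_FOODS, FOODS, content_vector, count_column

logger = logging.getLogger(__name__)


def fit_term_model(
    food_counts: np.ndarray, ask_flags: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """OLS linear probability model of an ask indicator on food counts.

    Parameters
    ----------
    food_counts
        (n_users x n_foods) matrix of raw search counts.
    ask_flags
        Boolean (or 0/1) vector of length n_users; must not be constant.

    Returns
    -------
    ``(coefficients, intercept, r2)``. A rank-deficient design is solved by
    the minimum-norm least-squares solution with a logged warning.
    """
    x = np.asarray(food_counts, dtype=float)
    y = np.asarray(ask_flags, dtype=float)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("food_counts must be (n_users x n_foods) matching ask_flags")
    if y.min() == y.max():
        raise ValueError("ask_flags are constant; R2 is undefined")
    design = np.column_stack([np.ones(len(x)), x])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d of %d); minimum-norm solution used",
            rank, design.shape[1],
        )
    fitted = design @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return beta[1:], float(beta[0]), r2


def compute_cob12(
    coefficients: np.ndarray,
    foods: pd.DataFrame,
    food_names: tuple[str, ...] = B12_FOODS,
    method: str = "pearson",
) -> float:
    """Correlation between per-food model coefficients and B12 contents.

    ``coefficients`` must be aligned with ``food_names`` (the 11 B12 foods
    by default; tomatoes are excluded from the content vector). Returns NaN
    with a logged warning when the coefficient vector has zero variance.
    """
    beta = np.asarray(coefficients, dtype=float)
    contents = content_vector(foods, food_names)
    if len(beta) != len(contents):
        raise ValueError(
            f"coefficient vector length {len(beta)} != {len(contents)} foods"
        )
    if np.ptp(beta) == 0:
        logger.warning("zero-variance coefficient vector; CoB12 undefined")
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(beta, contents).statistic)
    if method == "spearman":
        return float(stats.spearmanr(beta, contents).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def fit_term_model_logistic(
    food_counts: np.ndarray, ask_flags: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Logistic alternative to the linear probability model.

    Returns ``(coefficients, intercept, pseudo_r2)`` with McFadden's
    pseudo-R2 in place of the OLS coefficient of determination.
    """
    import statsmodels.api as sm

    x = np.asarray(food_counts, dtype=float)
    y = np.asarray(ask_flags, dtype=float)
    if y.min() == y.max():
        raise ValueError("ask_flags are constant; fit is undefined")
    fit = sm.Logit(y, sm.add_constant(x, has_constant="add")).fit(disp=False)
    return fit.params[1:], float(fit.params[0]), float(fit.prsquared)


def fit_all_terms(
    profiles: pd.DataFrame,
    foods: pd.DataFrame,
    lexicon,
    include_tomato: bool = False,
    cob12_method: str = "pearson",
    drop_zero_count_users: bool = False,
    model: str = "ols",
) -> pd.DataFrame:
    """Fit the per-term model for every lexicon term present in the profiles.

    Predictors are the raw counts of the 11 B12 foods; ``include_tomato``
    adds tomato counts as a 12th predictor (used by the negative-control
    coefficient check; CoB12 is always computed over the B12 foods).
    ``model`` selects the fit: ``"ols"`` (linear probability model, the
    default; r2i is the coefficient of determination) or ``"logistic"``
    (r2i is McFadden's pseudo-R2). Terms
    with constant ask flags are skipped with a log message.

    Returns a DataFrame with columns ``term``, ``set``, ``n_askers``,
    ``r2i``, ``cob12``, one ``coef_<food>`` column per predictor, and
    ``intercept``.
    """
    if model not in ("ols", "logistic"):
        raise ValueError(f"unknown model {model!r}")
    fitter = fit_term_model if model == "ols" else fit_term_model_logistic
    predictor_foods = FOODS if include_tomato else B12_FOODS
    cols = [count_column(f) for f in predictor_foods]
    data = profiles
    if drop_zero_count_users:
        data = data[data[cols].sum(axis=1) > 0]
    x = data[cols].to_numpy(dtype=float)
    n_b12 = len(B12_FOODS)
    rows = []
    for term in lexicon.terms:
        col = f"term_{term}"
        if col not in data.columns:
            logger.info("term %r absent from profiles; skipped", term)
            continue
        y = data[col].to_numpy(dtype=bool)
        n_askers = int(y.sum())
        if n_askers == 0 or n_askers == len(y):
            logger.info("term %r has constant ask flags; skipped", term)
            continue
        beta, intercept, r2 = fitter(x, y)
        cob12 = compute_cob12(beta[:n_b12], foods, B12_FOODS, cob12_method)
        row = {
            "term": term,
            "set": lexicon.set_of(term),
            "n_askers": n_askers,
            "r2i": r2,
            "cob12": cob12,
        }
        for food, b in zip(predictor_foods, beta):
            row[f"coef_{food}"] = b
        row["intercept"] = intercept
        rows.append(row)
    return pd.DataFrame(rows)


def rank_terms(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k terms by R2I (ties: larger n_askers first, then term label)."""
    if len(results) == 0:
        raise ValueError("empty results table")
    ordered = results.sort_values(
        ["r2i", "n_askers", "term"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return ordered.head(k)


def contrast_sets(results: pd.DataFrame, k: int = 10) -> dict:
    """Target-vs-control contrast of R2I (top-k medians) and CoB12 (means).

    Returns median top-k R2I per set and their ratio with a rank-sum p on
    the two top-k samples, plus full-set mean CoB12 per set with a rank-sum
    p. ``k`` is lowered (with a log message) when a set has fewer terms.
    """
    target = results[results["set"] == "target"]
    control = results[results["set"] == "control"]
    if len(target) == 0 or len(control) == 0:
        raise ValueError("both target and control sets must be nonempty")
    k_eff = min(k, len(target), len(control))
    if k_eff < k:
        logger.info("top-k lowered from %d to %d (set sizes)", k, k_eff)
    top_t = rank_terms(target, k_eff)["r2i"].to_numpy()
    top_c = rank_terms(control, k_eff)["r2i"].to_numpy()
    cob_t = target["cob12"].dropna().to_numpy()
    cob_c = control["cob12"].dropna().to_numpy()
    med_c = float(np.median(top_c))
    return {
        "median_r2i_target": float(np.median(top_t)),
        "median_r2i_control": med_c,
        "median_ratio": float(np.median(top_t) / med_c) if med_c > 0 else float("inf"),
        "r2i_ranksum_p": ranksum_test(top_t, top_c),
        "mean_cob12_target": float(cob_t.mean()),
        "mean_cob12_control": float(cob_c.mean()),
        "cob12_ranksum_p": ranksum_test(cob_t, cob_c),
        "k": k_eff,
    }


def popularity_correlations(results: pd.DataFrame) -> dict:
    """Spearman correlations of R2I with popularity and with CoB12.

    ``rho_r2i_vs_n`` is computed over the target set (asker counts vs fit
    quality); the R2I-CoB12 correlation is reported separately for targets
    and controls, each with its two-sided p-value.
    """
    target = results[results["set"] == "target"]
    control = results[results["set"] == "control"]
    out = {}
    if len(target) >= 3:
        r, p = stats.spearmanr(target["r2i"], target["n_askers"])
        out["rho_r2i_vs_n"] = float(r)
        out["p_r2i_vs_n"] = float(p)
        r, p = stats.spearmanr(target["r2i"], target["cob12"])
        out["rho_r2i_vs_cob12_target"] = float(r)
        out["p_r2i_vs_cob12_target"] = float(p)
    if len(control) >= 3:
        r, p = stats.spearmanr(control["r2i"], control["cob12"])
        out["rho_r2i_vs_cob12_control"] = float(r)
        out["p_r2i_vs_cob12_control"] = float(p)
    return out


def tomato_check(results: pd.DataFrame) -> dict:
    """Ratio of mean absolute coefficients: B12 foods vs the tomato control.

    Requires models fitted with ``include_tomato=True``. Returns the
    term-averaged mean |coefficient| over the 11 B12 foods, the
    term-averaged |tomato coefficient| and their ratio (inf, flagged, when
    the tomato average is exactly 0).
    """
    if "coef_tomatoes" not in results.columns:
        raise ValueError("tomato predictor absent; fit with include_tomato=True")
    b12_cols = [f"coef_{f}" for f in B12_FOODS]
    mean_b12 = float(results[b12_cols].abs().mean(axis=1).mean())
    mean_tomato = float(results["coef_tomatoes"].abs().mean())
    infinite = mean_tomato == 0.0
    ratio = float("inf") if infinite else mean_b12 / mean_tomato
    return {
        "mean_abs_coef_b12_foods": mean_b12,
        "mean_abs_coef_tomato": mean_tomato,
        "ratio": ratio,
        "ratio_infinite": infinite,
    }
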