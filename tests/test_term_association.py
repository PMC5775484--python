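import numpy as np
import pandas as pd
import pytest

import b12search as b
from b12search.reference import B12_FOODS


def _results_frame(rows):
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- OLS fit

def test_noiseless_linear_flags_recovered_exactly(rng):
    """Ask flags that ARE a linear function of counts give r2=1 and exact
    coefficients."""
    x = rng.integers(0, 2, size=(200, 11)).astype(float)
    y = x[:, 0]  # 0/1-valued linear function: weight 1 on food 0
    beta, intercept, r2 = b.fit_term_model(x, y)
    assert r2 == pytest.approx(1.0, abs=1e-12)
    expected = np.zeros(11)
    expected[0] = 1.0
    np.testing.assert_allclose(beta, expected, atol=1e-8)
    assert intercept == pytest.approx(0.0, abs=1e-8)


def test_null_r2_shrinks_with_n(rng):
    """Independent flags: R2 concentrates near p/(n-1)."""
    n, p = 100_000, 12
    x = rng.poisson(2.0, size=(n, p)).astype(float)
    y = (rng.random(n) < 0.05).astype(float)
    _, _, r2 = b.fit_term_model(x, y)
    assert r2 < 0.001


def test_three_user_toy_matches_normal_equations():
    """Hand-solved 3x3 system: intercept -1, unit weights on both foods."""
    x = np.zeros((3, 11))
    x[0, 0] = 1
    x[1, 1] = 1
    x[2, 0] = x[2, 1] = 1
    y = np.array([0.0, 0.0, 1.0])
    beta, intercept, r2 = b.fit_term_model(x, y)
    assert intercept == pytest.approx(-1.0, abs=1e-10)
    assert beta[0] == pytest.approx(1.0, abs=1e-10)
    assert beta[1] == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(beta[2:], 0.0, atol=1e-10)  # min-norm on unused foods
    assert r2 == pytest.approx(1.0)


def test_constant_flags_rejected():
    with pytest.raises(ValueError, match="constant"):
        b.fit_term_model(np.ones((20, 3)), np.zeros(20))


def test_ols_matches_explicit_normal_equations(rng):
    """lstsq solution equals (X'X)^-1 X'y on random well-posed designs."""
    for _ in range(100):
        n = rng.integers(15, 51)
        p = rng.integers(2, 9)
        x = rng.normal(size=(n, p))
        y = (rng.random(n) < 0.4).astype(float)
        if y.min() == y.max():
            continue
        beta, intercept, _ = b.fit_term_model(x, y)
        design = np.column_stack([np.ones(n), x])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(
            np.concatenate([[intercept], beta]), oracle, atol=1e-8
        )


def test_column_permutation_equivariance(rng):
    x = rng.poisson(1.0, size=(500, 11)).astype(float)
    y = (rng.random(500) < 0.3).astype(float)
    beta, intercept, r2 = b.fit_term_model(x, y)
    perm = rng.permutation(11)
    beta_p, intercept_p, r2_p = b.fit_term_model(x[:, perm], y)
    np.testing.assert_allclose(beta_p, beta[perm], atol=1e-10)
    assert r2_p == pytest.approx(r2, abs=1e-12)
    assert intercept_p == pytest.approx(intercept, abs=1e-10)


# ---------------------------------------------------------------- CoB12

def test_cob12_perfect_anticorrelation(foods):
    contents = b.content_vector(foods, B12_FOODS)
    assert b.compute_cob12(-contents, foods) == pytest.approx(-1.0)
    assert b.compute_cob12(contents + 7.0, foods) == pytest.approx(1.0)


def test_cob12_textbook_pearson_oracle(foods):
    """Fixed vector 1..11 vs the content vector, Pearson by explicit sums."""
    beta = np.arange(1.0, 12.0)
    c = b.content_vector(foods, B12_FOODS)
    n = len(c)
    num = n * (beta * c).sum() - beta.sum() * c.sum()
    den = np.sqrt(n * (beta**2).sum() - beta.sum() ** 2) * np.sqrt(
        n * (c**2).sum() - c.sum() ** 2
    )
    assert b.compute_cob12(beta, foods) == pytest.approx(num / den, abs=1e-12)


def test_cob12_zero_variance_is_nan(foods):
    assert np.isnan(b.compute_cob12(np.ones(11), foods))


def test_cob12_affine_invariance(foods, rng):
    beta = rng.normal(size=11)
    base = b.compute_cob12(beta, foods)
    assert b.compute_cob12(3.5 * beta + 2.0, foods) == pytest.approx(base, abs=1e-12)
    doubled = b.generate_food_reference(
        overrides={f: 2.0 * v + 1.0 for f, v in
                   zip(B12_FOODS, b.content_vector(foods, B12_FOODS))}
    )
    assert b.compute_cob12(beta, doubled) == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------- ranking

def test_rank_terms_tie_rules():
    res = _results_frame(
        [
            {"term": "b", "set": "target", "n_askers": 10, "r2i": 0.2, "cob12": 0.0},
            {"term": "a", "set": "target", "n_askers": 5, "r2i": 0.2, "cob12": 0.0},
            {"term": "c", "set": "target", "n_askers": 1, "r2i": 0.5, "cob12": 0.0},
        ]
    )
    ranked = b.rank_terms(res, k=10)  # k beyond size: full sorted table
    assert list(ranked["term"]) == ["c", "b", "a"]
    assert len(b.rank_terms(res, k=2)) == 2


def test_contrast_sets_symmetry():
    rows = [
        {"term": f"t{i}", "set": "target", "n_askers": 10 + i, "r2i": 0.01 * i,
         "cob12": -0.1 * i}
        for i in range(12)
    ]
    mirror = [dict(r, set="control", term=f"c{r['term']}") for r in rows]
    sc = b.contrast_sets(_results_frame(rows + mirror), k=10)
    assert sc["median_ratio"] == pytest.approx(1.0)
    assert sc["mean_cob12_target"] == pytest.approx(sc["mean_cob12_control"])


def test_contrast_sets_requires_both_sets():
    rows = [{"term": "t", "set": "target", "n_askers": 5, "r2i": 0.1, "cob12": 0.0}]
    with pytest.raises(ValueError):
        b.contrast_sets(_results_frame(rows))


def test_popularity_correlation_monotone():
    rows = [
        {"term": f"t{i}", "set": "target", "n_askers": i, "r2i": 0.001 * i,
         "cob12": -0.05 * i}
        for i in range(1, 9)
    ]
    out = b.popularity_correlations(_results_frame(rows))
    assert out["rho_r2i_vs_n"] == pytest.approx(1.0)
    assert out["rho_r2i_vs_cob12_target"] == pytest.approx(-1.0)


def test_spearman_with_tie_matches_brute_force():
    """5-point example with one tie, average-rank Spearman by hand."""
    from scipy import stats

    r2i = np.array([0.1, 0.2, 0.2, 0.4, 0.5])
    n = np.array([3.0, 1.0, 4.0, 2.0, 5.0])

    def avg_ranks(x):
        order = np.argsort(x)
        ranks = np.empty(len(x))
        i = 0
        s = x[order]
        while i < len(x):
            j = i
            while j + 1 < len(x) and s[j + 1] == s[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    ra, rb = avg_ranks(r2i), avg_ranks(n)
    expected = np.corrcoef(ra, rb)[0, 1]
    assert stats.spearmanr(r2i, n).statistic == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- tomato

def test_tomato_check_degenerate_and_symmetric():
    base = {f"coef_{f}": 1.0 for f in B12_FOODS}
    rows = [dict(term="t", set="target", n_askers=5, r2i=0.1, cob12=0.0,
                 coef_tomatoes=0.0, **base)]
    out = b.tomato_check(_results_frame(rows))
    assert out["ratio_infinite"] and np.isinf(out["ratio"])
    rows[0]["coef_tomatoes"] = 1.0
    out = b.tomato_check(_results_frame(rows))
    assert out["ratio"] == pytest.approx(1.0)


def test_tomato_check_requires_tomato_predictor():
    rows = [{"term": "t", "set": "target", "n_askers": 5, "r2i": 0.1, "cob12": 0.0}]
    with pytest.raises(ValueError, match="tomato"):
        b.tomato_check(_results_frame(rows))


def test_tomato_carries_no_signal_when_asks_track_b12(big_sim, foods):
    """With intake-driven asking, B12-food coefficients dominate tomato's."""
    res = b.fit_all_terms(
        big_sim["profiles"], foods, big_sim["lexicon"], include_tomato=True
    )
    out = b.tomato_check(res[res["set"] == "target"])
    assert out["ratio"] > 1.0


# ---------------------------------------------------------------- recovery

def test_cob12_decreases_with_effect_strength():
    """Median fitted CoB12 is monotone decreasing in the generative effect
    size (0 < 0.2 < 0.5 < 1.0 x base scale), over 20 seeds."""
    levels = {"e000": 0.0, "e020": -0.004, "e050": -0.01, "e100": -0.02}
    cob = {t: [] for t in levels}
    foods = b.generate_food_reference()
    for seed in range(20):
        cfg = b.SimulationConfig(
            seed=100 + seed, n_users=8000, n_recipes=200,
            term_effects=dict(levels),
            baseline_term_rates={t: 0.05 for t in levels},
        )
        recipes = b.generate_recipe_corpus(cfg)
        _, truth = b.generate_search_log(cfg, recipes)
        x = truth.emitted_counts[[f"count_{f}" for f in B12_FOODS]].to_numpy(float)
        for term in levels:
            y = truth.term_asks[term].to_numpy(float)
            if y.min() == y.max():
                continue
            beta, _, _ = b.fit_term_model(x, y)
            cob[term].append(b.compute_cob12(beta, foods))
    med = {t: np.median(v) for t, v in cob.items()}
    assert med["e100"] < med["e050"] < med["e020"] < 0.3
    assert med["e100"] < -0.3  # strong effects give clearly negative CoB12


def test_logistic_model_option_recovers_direction(big_sim, foods):
    """The logistic fit (pseudo-R2) agrees with OLS on CoB12 direction."""
    prof = big_sim["profiles"].iloc[:10_000]
    lex = big_sim["lexicon"]
    ols = b.fit_all_terms(prof, foods, lex, model="ols")
    logi = b.fit_all_terms(prof, foods, lex, model="logistic")
    merged = ols.merge(logi, on="term", suffixes=("_ols", "_logit"))
    strong = merged[merged["term"] == "target00"].iloc[0]
    assert strong["cob12_ols"] < 0 and strong["cob12_logit"] < 0
    assert (logi["r2i"] >= 0).all()
    with pytest.raises(ValueError, match="unknown model"):
        b.fit_all_terms(prof, foods, lex, model="probit")
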