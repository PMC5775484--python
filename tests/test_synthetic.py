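import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats

import b12search as b
from b12search.reference import FOODS, COUNT_COLUMNS


def _small_config(**kw):
    effects = {"target00": kw.pop("effect", -0.05), "control00": 0.0}
    rates = {t: 0.05 for t in effects}
    defaults = dict(
        seed=5, n_users=2000, n_recipes=100,
        term_effects=effects, baseline_term_rates=rates,
    )
    defaults.update(kw)
    return b.SimulationConfig(**defaults)


# ---------------------------------------------------------------- config

@pytest.mark.parametrize(
    "bad",
    [
        {"n_users": 0},
        {"awareness_rate": 1.5},
        {"awareness_intake_shift": 0.2},
        {"diet_concentration": 0.0},
        {"baseline_term_rates": {"target00": 0.0, "control00": 0.05}},
        {"term_effects": {"other": -1.0}},
    ],
)
def test_config_validation_rejects(bad):
    with pytest.raises(ValueError):
        _small_config(**bad)


# ---------------------------------------------------------------- corpus

def test_corpus_deterministic_and_valid():
    cfg = _small_config()
    a = b.generate_recipe_corpus(cfg)
    c = b.generate_recipe_corpus(cfg)
    assert_frame_equal(a, c)
    assert len(a) == cfg.n_recipes
    assert a["recipe_id"].is_unique
    assert all(1 <= len(i.split(";")) <= 3 for i in a["ingredients"])
    assert all(set(i.split(";")) <= set(FOODS) for i in a["ingredients"])
    # title contains every ingredient as a token
    for title, ing in zip(a["title"], a["ingredients"]):
        assert set(ing.split(";")) <= set(title.split())


def test_corpus_ingredient_histogram_matches_multinomial():
    """Uniform ingredient weights give a uniform ingredient histogram."""
    cfg = _small_config(n_recipes=10_000)
    corpus = b.generate_recipe_corpus(cfg)
    counts = np.zeros(len(FOODS))
    total = 0
    for ing in corpus["ingredients"]:
        for food in ing.split(";"):
            counts[FOODS.index(food)] += 1
            total += 1
    # under uniform weights each food is equally likely in every draw
    _, p = stats.chisquare(counts, f_exp=np.full(len(FOODS), total / len(FOODS)))
    assert p > 0.01


# ---------------------------------------------------------------- log

def test_log_deterministic_and_seed_sensitive():
    cfg = _small_config()
    recipes = b.generate_recipe_corpus(cfg)
    ev1, _ = b.generate_search_log(cfg, recipes)
    ev2, _ = b.generate_search_log(cfg, recipes)
    assert_frame_equal(ev1, ev2)
    other = _small_config(seed=6)
    ev3, _ = b.generate_search_log(other, b.generate_recipe_corpus(other))
    assert not ev1.equals(ev3)


def test_empty_corpus_rejected():
    cfg = _small_config()
    with pytest.raises(ValueError, match="empty"):
        b.generate_search_log(cfg, b.generate_recipe_corpus(cfg).iloc[:0])


def test_latent_intake_is_expected_estimator(big_sim, foods):
    """Latent intake equals contents dotted with expected counts exactly,
    and matches the estimator on realized counts up to sampling error."""
    truth = big_sim["truth"]
    contents = b.content_vector(foods)
    expected = truth.expected_counts[list(COUNT_COLUMNS)].to_numpy() @ contents
    np.testing.assert_allclose(expected, truth.users["latent_intake"], rtol=1e-12)
    realized = truth.emitted_counts[list(COUNT_COLUMNS)].to_numpy() @ contents
    mean_intake = truth.users["latent_intake"].mean()
    assert abs(realized.mean() - mean_intake) / mean_intake < 0.02


def test_latent_intake_scales_with_search_rate():
    """Doubling the recipe-query rate doubles latent intake exactly."""
    cfg1 = _small_config(mean_food_searches=4.0)
    cfg2 = _small_config(mean_food_searches=8.0)
    recipes = b.generate_recipe_corpus(cfg1)
    _, t1 = b.generate_search_log(cfg1, recipes)
    _, t2 = b.generate_search_log(cfg2, recipes)
    np.testing.assert_allclose(
        2.0 * t1.users["latent_intake"], t2.users["latent_intake"], rtol=1e-12
    )


def test_null_effects_leave_asking_independent_of_intake(null_sim):
    """With all effects zero a logistic refit finds no intake slope."""
    import statsmodels.api as sm

    truth = null_sim["truth"]
    intake = truth.users["latent_intake"].to_numpy()
    x = sm.add_constant(intake - intake.mean())
    y = truth.term_asks["target00"].to_numpy().astype(float)
    fit = sm.Logit(y, x).fit(disp=False)
    lo, hi = fit.conf_int()[1]
    assert lo < 0 < hi


def test_negative_effect_lowers_asker_intake(big_sim):
    """Askers of a negative-effect term have lower latent intake (ranksum)."""
    truth = big_sim["truth"]
    intake = truth.users["latent_intake"].to_numpy()
    ask = truth.term_asks["target00"].to_numpy()
    assert intake[ask].mean() < intake[~ask].mean()
    assert b.ranksum_test(intake[ask], intake[~ask]) < 0.01


def test_supplement_rates_match_conditionals(big_sim):
    """Observed supplement rates per awareness group sit in binomial bands."""
    cfg, truth = big_sim["config"], big_sim["truth"]
    aware = truth.users["aware"].to_numpy()
    supp = truth.events[truth.events["kind"] == "b12_supplement"]["user_id"]
    asked = truth.users["user_id"].isin(set(supp)).to_numpy()
    for mask, p in ((aware, cfg.supplement_given_awareness),
                    (~aware, cfg.supplement_given_no_awareness)):
        n = mask.sum()
        rate = asked[mask].mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < 4 * se + 1e-12


def test_awareness_always_triggers_deficiency_query(big_sim):
    truth = big_sim["truth"]
    aware_users = set(truth.users.loc[truth.users["aware"], "user_id"])
    def_users = set(
        truth.events.loc[truth.events["kind"] == "b12_deficiency", "user_id"]
    )
    assert aware_users == def_users


# ------------------------------------------------------- expenditure

def test_expenditure_rows_are_simplex(big_sim, foods):
    exp = b.generate_regional_expenditure(
        big_sim["truth"], big_sim["recipes"], foods, big_sim["config"]
    )
    sums = exp.groupby("region")["fraction"].sum()
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    assert (exp["fraction"] >= 0).all()


def test_noiseless_expenditure_equals_query_fractions(big_sim, foods):
    cfg = b.SimulationConfig(**{**big_sim["config"].to_dict(), "expenditure_noise_sd": 0.0})
    exp = b.generate_regional_expenditure(big_sim["truth"], big_sim["recipes"], foods, cfg)
    ours = b.consumption.regional_query_fractions(big_sim["profiles"], foods)
    merged = ours.merge(exp, on=["region", "category"])
    np.testing.assert_allclose(merged["fraction_x"], merged["fraction_y"], atol=1e-12)


def test_expenditure_noise_monte_carlo_envelope(big_sim, foods):
    """sd=0.05 noise on 4x6 fraction cells keeps r in the simulated envelope."""
    cfg = b.SimulationConfig(**{**big_sim["config"].to_dict(), "expenditure_noise_sd": 0.05})
    rs = []
    for s in range(100):
        exp = b.generate_regional_expenditure(
            big_sim["truth"], big_sim["recipes"], foods, cfg,
            rng=np.random.default_rng([s, 99]),
        )
        r, _, n = b.validate_regional(big_sim["profiles"], foods, exp)
        assert n == 24
        rs.append(r)
    assert all(0.4 < r < 0.999 for r in rs)


# ------------------------------------------------------- indications

def test_indication_counts_valid_and_explicit_passthrough():
    cfg = _small_config(indication_params={"target00": (12, 3), "control00": (5, 0)})
    ind = b.generate_indications(["target00", "control00"], cfg)
    assert ind.set_index("term").loc["target00"].tolist() == [12, 3]
    drawn = b.generate_indications(
        ["target00", "control00"], _small_config()
    )
    assert (drawn["n_pain_indications"] <= drawn["n_indications"]).all()
    assert (drawn["n_indications"] >= 1).all()


def test_coupled_indications_track_popularity():
    """Coupling on: indication counts correlate with asker counts at 50 terms."""
    rng = np.random.default_rng(3)
    effects = {f"target{i:02d}": 0.0 for i in range(50)}
    rates = {t: float(np.exp(rng.uniform(np.log(0.005), np.log(0.2)))) for t in effects}
    cfg = b.SimulationConfig(
        seed=9, n_users=5000, n_recipes=100,
        term_effects=effects, baseline_term_rates=rates,
        indication_params=b.IndicationSettings(coupled=True),
    )
    recipes = b.generate_recipe_corpus(cfg)
    _, truth = b.generate_search_log(cfg, recipes)
    n_askers = truth.term_asks[list(cfg.terms)].sum().to_numpy()
    ind = b.generate_indications(list(cfg.terms), cfg)
    rho, p = stats.spearmanr(ind["n_indications"], n_askers)
    assert rho > 0 and p < 0.01


def test_uncoupled_indications_independent_of_popularity():
    """Coupling off: correlation with popularity stays within the null band."""
    rng = np.random.default_rng(4)
    effects = {f"target{i:02d}": 0.0 for i in range(50)}
    rates = {t: float(np.exp(rng.uniform(np.log(0.005), np.log(0.2)))) for t in effects}
    cfg = b.SimulationConfig(
        seed=9, n_users=1000, n_recipes=50,
        term_effects=effects, baseline_term_rates=rates,
        indication_params=b.IndicationSettings(coupled=False),
    )
    hits = 0
    for s in range(20):
        ind = b.generate_indications(
            list(cfg.terms), cfg, rng=np.random.default_rng([s, 4])
        )
        rates_arr = np.array([rates[t] for t in cfg.terms])
        _, p = stats.spearmanr(ind["n_indications"], rates_arr)
        hits += p < 0.05
    assert hits <= 4  # ~binomial(20, .05) upper band
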