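import numpy as np
import pandas as pd
import pytest

import b12search as b


@pytest.fixture(scope="session")
def foods():
    return b.generate_food_reference()


@pytest.fixture(scope="session")
def tiny_corpus():
    """Three hand-built recipes for matcher unit tests."""
    return pd.DataFrame(
        {
            "recipe_id": ["r00000", "r00001", "r00002"],
            "title": ["chicken soup", "beef egg casserole", "salmon baked"],
            "ingredients": ["chicken", "beef;egg", "salmon"],
        }
    )


@pytest.fixture(scope="session")
def tiny_index(tiny_corpus):
    return b.RecipeIndex(tiny_corpus)


@pytest.fixture(scope="session")
def lexicon():
    return b.TermLexicon(
        target_terms=("gabapentin", "tramadol", "back pain"),
        control_terms=("acne", "warfarin"),
    )


def _sim_lexicon(effects):
    return b.TermLexicon(
        target_terms=tuple(t for t in sorted(effects) if t.startswith("target")),
        control_terms=tuple(t for t in sorted(effects) if t.startswith("control")),
    )


@pytest.fixture(scope="session")
def big_sim():
    """One powered 50k-user simulation shared across property tests.

    Awareness is raised above the study default to give the awareness-linked
    checks (deficiency contrast, supplement contingency) adequate group
    sizes at this n.
    """
    effects, rates = b.recovery_term_config(seed=11, n_targets=5, n_controls=5)
    effects["target00"] = -0.05  # one strong term for the ranksum check
    config = b.SimulationConfig(
        seed=11,
        n_users=50_000,
        term_effects=effects,
        baseline_term_rates=rates,
        awareness_rate=0.01,
        supplement_given_awareness=0.04,
        supplement_given_no_awareness=0.0003,
    )
    recipes = b.generate_recipe_corpus(config)
    events, truth = b.generate_search_log(config, recipes)
    lex = _sim_lexicon(effects)
    index = b.RecipeIndex(recipes)
    profiles = b.aggregate_users(events, index, lex)
    return {
        "config": config,
        "recipes": recipes,
        "events": events,
        "truth": truth,
        "lexicon": lex,
        "index": index,
        "profiles": profiles,
    }


@pytest.fixture(scope="session")
def null_sim():
    """50k-user simulation with every term effect exactly zero."""
    effects = {f"target{i:02d}": 0.0 for i in range(3)}
    effects |= {f"control{i:02d}": 0.0 for i in range(3)}
    rates = {t: 0.03 for t in effects}
    config = b.SimulationConfig(
        seed=12,
        n_users=50_000,
        term_effects=effects,
        baseline_term_rates=rates,
    )
    recipes = b.generate_recipe_corpus(config)
    events, truth = b.generate_search_log(config, recipes)
    return {"config": config, "recipes": recipes, "events": events, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
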