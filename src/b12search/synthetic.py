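"""Seeded synthetic stand-ins for the proprietary inputs of the study design.

The original analysis consumed a month of search-engine queries (user id,
query text, region) plus reference tables: B12 content per food, regional
food-expenditure fractions, food costs, and per-drug indication counts from
an adverse-reaction database. None of those logs are publicly available, so
this module generates statistically structured substitutes with recorded
ground truth, letting every downstream stage be tested by parameter
recovery.

Generative model, per user:

1. a diet preference vector over the 12 tracked ingredient foods is drawn
   from a Dirichlet with a single concentration knob;
2. a Poisson number of recipe queries is emitted; each query first picks a
   food by preference, then a recipe containing that food uniformly, and its
   text is the recipe title plus the token "recipe";
3. latent B12 intake is the expectation of the analysis-stage consumption
   estimator under that preference (contents in mcg/100 g times expected
   food search counts);
4. each medical term is asked with probability given by a logistic model in
   centered latent intake (negative effects: low intake -> more asking);
5. a small awareness fraction of users tilts its preference toward low-B12
   foods, always asks a "b12 deficiency" query, and asks about supplements
   with an elevated probability.

Everything is deterministic given (config, seed); all randomness flows
through ``numpy.random.default_rng`` seeded with (seed, stage) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .reference import (
    DEFAULT_CATEGORY_MAP,
    FOODS,
    content_vector,
    count_column,
    generate_food_reference,
)

logger = logging.getLogger(__name__)

# Tokens that pad recipe titles; disjoint from food names and query keywords.
TITLE_FILLERS = (
    "soup", "stew", "salad", "roast", "grilled", "baked", "fried", "easy",
    "quick", "homemade", "classic", "spicy", "creamy", "crispy", "glazed",
    "smoked", "stuffed", "casserole", "curry", "chowder", "skillet",
    "marinated", "herb", "garlic",
)

# Queries with no food, recipe, B12 or medical content.
NOISE_QUERIES = (
    "weather tomorrow", "news today", "movie showtimes", "football scores",
    "cheap flights", "used cars", "tv guide", "daily horoscope",
    "traffic map", "lottery numbers",
)

DEFICIENCY_QUERIES = (
    "b12 deficiency",
    "b12 deficiency symptoms",
    "vitamin b12 deficiency",
)
SUPPLEMENT_QUERIES = (
    "b12 supplements",
    "vitamin b12 supplement",
    "b12 injections",
    "b12 pills",
)
TERM_SUFFIXES = ("", "dosage", "side effects", "reviews")

# Default medical terms: pain/neuropsychiatric targets (negative intake
# effects) and controls expected to be unrelated to B12 intake.
DEFAULT_TARGET_TERMS = (
    "gabapentin", "tramadol", "neuropathy", "omeprazole", "sertraline",
    "citalopram", "oxycodone", "duloxetine", "trazodone",
)
DEFAULT_CONTROL_TERMS = (
    "acne", "allergy", "asthma", "bronchitis", "cataract", "eczema",
    "insulin", "statin", "warfarin",
)


@dataclass
class IndicationSettings:
    """Generator settings for per-drug indication counts.

    With ``coupled=True`` the expected number of indications increases with
    term popularity and with the magnitude of the term's (negative) intake
    effect, while the pain share of indications increases as the effect
    weakens; this encodes the hypothesized structure that broad-spectrum
    drugs dilute the intake signal and pain-specific drugs concentrate it.
    """

    coupled: bool = True
    base_n: float = 20.0
    popularity_coef: float = 0.6
    effect_coef: float = 0.8
    pain_base_logit: float = -1.0
    pain_effect_coef: float = 1.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic search-log generator.

    ``term_effects`` maps each medical term to the shift in log-odds of
    asking about it per mcg of centered latent B12 intake (negative for
    target terms, 0 for controls); ``baseline_term_rates`` gives each term's
    population ask probability at mean intake.
    """

    seed: int
    n_users: int = 50_000
    n_recipes: int = 500
    mean_food_searches: float = 8.0
    mean_noise_searches: float = 2.0
    diet_concentration: float = 2.0
    term_effects: dict[str, float] = field(
        default_factory=lambda: (
            {t: -0.01 for t in DEFAULT_TARGET_TERMS}
            | {t: 0.0 for t in DEFAULT_CONTROL_TERMS}
        )
    )
    baseline_term_rates: dict[str, float] = field(
        default_factory=lambda: (
            {t: 0.03 for t in DEFAULT_TARGET_TERMS}
            | {t: 0.03 for t in DEFAULT_CONTROL_TERMS}
        )
    )
    awareness_rate: float = 5.6e-4
    awareness_intake_shift: float = -2.0
    supplement_given_awareness: float = 0.0383
    supplement_given_no_awareness: float = 2.53e-4
    n_regions: int = 4
    expenditure_noise_sd: float = 0.05
    indication_params: dict[str, tuple[int, int]] | IndicationSettings | None = None
    ingredient_weights: dict[str, float] | None = None
    term_query_suffix_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.n_users < 1 or self.n_recipes < 1:
            raise ValueError("n_users and n_recipes must be >= 1")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.diet_concentration <= 0:
            raise ValueError("diet_concentration must be positive")
        if self.mean_food_searches < 0 or self.mean_noise_searches < 0:
            raise ValueError("mean search rates must be nonnegative")
        if self.awareness_intake_shift > 0:
            raise ValueError("awareness_intake_shift must be <= 0")
        for name in (
            "awareness_rate",
            "supplement_given_awareness",
            "supplement_given_no_awareness",
            "term_query_suffix_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if set(self.term_effects) != set(self.baseline_term_rates):
            raise ValueError("term_effects and baseline_term_rates must share keys")
        for term, rate in self.baseline_term_rates.items():
            if not 0.0 < rate < 1.0:
                raise ValueError(f"baseline rate for {term!r} must be in (0, 1)")
        if self.expenditure_noise_sd < 0:
            raise ValueError("expenditure_noise_sd must be nonnegative")
        if self.ingredient_weights is not None:
            unknown = set(self.ingredient_weights) - set(FOODS)
            if unknown:
                raise ValueError(f"unknown foods in ingredient_weights: {sorted(unknown)}")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(sorted(self.term_effects))

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.indication_params, IndicationSettings):
            d["indication_params"] = {"settings": asdict(self.indication_params)}
        return d


@dataclass
class GroundTruth:
    """Generator-side truth recorded for testing; never read by analysis.

    ``events`` is aligned row-for-row with the emitted query log and records
    each event's kind and, for recipe queries, the true recipe id.
    """

    users: pd.DataFrame            # user_id, region, aware, latent_intake, n_recipe_queries
    expected_counts: pd.DataFrame  # user_id + expected per-food search counts
    emitted_counts: pd.DataFrame   # user_id + realized per-food tallies from true recipes
    events: pd.DataFrame           # kind, recipe_id (aligned with the log)
    term_asks: pd.DataFrame        # user_id + one boolean column per term
    term_effects: dict[str, float]
    config: SimulationConfig


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _ingredient_probs(config: SimulationConfig) -> np.ndarray:
    w = np.ones(len(FOODS))
    if config.ingredient_weights:
        for i, food in enumerate(FOODS):
            w[i] = config.ingredient_weights.get(food, 1.0)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("ingredient weights must be nonnegative and not all zero")
    return w / w.sum()


def generate_recipe_corpus(config: SimulationConfig) -> pd.DataFrame:
    """Generate ``n_recipes`` recipes over the 12 tracked foods.

    Each recipe has 1-3 ingredients (sampled by ``ingredient_weights``,
    uniform by default) and a title made of the ingredient names plus 1-2
    filler tokens, so a token matcher can recover the recipe from a query
    built from the title.

    Returns a DataFrame with columns ``recipe_id``, ``title`` (lowercase
    space-joined tokens) and ``ingredients`` (';'-joined food names).
    """
    rng = _rng(config, 1)
    probs = _ingredient_probs(config)
    n = config.n_recipes
    n_ing = rng.choice([1, 2, 3], size=n, p=[0.50, 0.35, 0.15])
    n_fill = rng.choice([1, 2], size=n, p=[0.5, 0.5])
    rows = []
    for i in range(n):
        ing = list(rng.choice(len(FOODS), size=n_ing[i], replace=False, p=probs))
        fillers = rng.choice(len(TITLE_FILLERS), size=n_fill[i], replace=False)
        ingredients = [FOODS[j] for j in ing]
        title = " ".join(ingredients + [TITLE_FILLERS[j] for j in fillers])
        rows.append((f"r{i:05d}", title, ";".join(ingredients)))
    return pd.DataFrame(rows, columns=["recipe_id", "title", "ingredients"])


def recipe_incidence(recipes: pd.DataFrame) -> np.ndarray:
    """Boolean (n_recipes x 12) matrix: recipe contains food."""
    idx = {f: i for i, f in enumerate(FOODS)}
    m = np.zeros((len(recipes), len(FOODS)), dtype=bool)
    for r, ing in enumerate(recipes["ingredients"]):
        for food in ing.split(";"):
            m[r, idx[food]] = True
    return m


def generate_search_log(
    config: SimulationConfig, recipes: pd.DataFrame
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the query-event log and record full ground truth.

    Returns ``(events, truth)`` where ``events`` has columns ``user_id``,
    ``text``, ``region`` (one query per row, grouped by user) and ``truth``
    is the :class:`GroundTruth` for the same run.
    """
    if len(recipes) == 0:
        raise ValueError("recipe corpus is empty")
    rng = _rng(config, 2)
    n = config.n_users
    foods = generate_food_reference()
    contents = content_vector(foods)           # length 12, tomatoes 0
    m = recipe_incidence(recipes)              # recipes x foods
    n_per_food = m.sum(axis=0)                 # recipes containing each food
    covered = n_per_food > 0

    # --- per-user latent structure -------------------------------------
    aware = rng.random(n) < config.awareness_rate
    alpha = np.full(len(FOODS), config.diet_concentration)
    gam = rng.standard_gamma(alpha, size=(n, len(FOODS)))
    pref = gam / gam.sum(axis=1, keepdims=True)
    if aware.any():
        # tilt aware users' preference away from B12-rich foods
        tilt = np.exp(config.awareness_intake_shift * contents / contents.max())
        pa = pref[aware] * tilt
        pref[aware] = pa / pa.sum(axis=1, keepdims=True)
    # preference restricted to foods that appear in >= 1 recipe
    pc = np.where(covered, pref, 0.0)
    pc = pc / pc.sum(axis=1, keepdims=True)

    # expected food counts per query: pick food j by preference, then a
    # uniform recipe containing j; every ingredient of that recipe counts.
    # B[j, i] = P(query picks food j lands on a recipe containing i).
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (m.T.astype(float) @ m.astype(float)) / n_per_food[:, None]
    b[~covered] = 0.0
    expected_per_query = pc @ b                       # users x foods
    expected_counts = config.mean_food_searches * expected_per_query
    intake = expected_counts @ contents               # latent mcg per user

    # --- recipe query events -------------------------------------------
    k_recipe = rng.poisson(config.mean_food_searches, size=n)
    u_rep = np.repeat(np.arange(n), k_recipe)
    cum = np.cumsum(pc, axis=1)
    draw = rng.random(len(u_rep))
    food_pick = (draw[:, None] > cum[u_rep]).sum(axis=1)
    # uniform recipe among those containing the picked food
    by_food = [np.flatnonzero(m[:, j]) for j in range(len(FOODS))]
    flat = np.concatenate([a for a in by_food if len(a)]) if any(covered) else np.array([], int)
    offsets = np.zeros(len(FOODS), dtype=int)
    pos = 0
    for j in range(len(FOODS)):
        offsets[j] = pos
        pos += len(by_food[j])
    slot = (rng.random(len(u_rep)) * n_per_food[food_pick]).astype(int)
    recipe_pick = flat[offsets[food_pick] + slot]

    emitted = np.zeros((n, len(FOODS)), dtype=np.int64)
    np.add.at(emitted, u_rep, m[recipe_pick].astype(np.int64))

    recipe_query = (recipes["title"] + " recipe").to_numpy(dtype=object)

    # --- term ask events ------------------------------------------------
    terms = config.terms
    centered = intake - intake.mean()
    ask = np.zeros((n, len(terms)), dtype=bool)
    for t_idx, term in enumerate(terms):
        lo = logit(config.baseline_term_rates[term])
        p = expit(lo + config.term_effects[term] * centered)
        ask[:, t_idx] = rng.random(n) < p

    # --- B12 and noise events -------------------------------------------
    supp_p = np.where(
        aware, config.supplement_given_awareness, config.supplement_given_no_awareness
    )
    asks_supplement = rng.random(n) < supp_p
    k_noise = rng.poisson(config.mean_noise_searches, size=n)

    # --- assemble the log -----------------------------------------------
    region = rng.integers(0, config.n_regions, size=n)
    user_ids = np.array([f"u{i:06d}" for i in range(n)], dtype=object)

    ev_user: list[np.ndarray] = [u_rep]
    ev_text: list[np.ndarray] = [recipe_query[recipe_pick]]
    ev_kind: list[np.ndarray] = [np.full(len(u_rep), "recipe", dtype=object)]
    ev_recipe: list[np.ndarray] = [recipes["recipe_id"].to_numpy(dtype=object)[recipe_pick]]

    def _add(users_idx: np.ndarray, texts: np.ndarray, kind: str) -> None:
        ev_user.append(users_idx)
        ev_text.append(texts)
        ev_kind.append(np.full(len(users_idx), kind, dtype=object))
        ev_recipe.append(np.full(len(users_idx), None, dtype=object))

    for t_idx, term in enumerate(terms):
        askers = np.flatnonzero(ask[:, t_idx])
        suffix = np.array(TERM_SUFFIXES, dtype=object)[
            np.where(
                rng.random(len(askers)) < config.term_query_suffix_rate,
                rng.integers(1, len(TERM_SUFFIXES), size=len(askers)),
                0,
            )
        ]
        texts = np.array(
            [term if s == "" else f"{term} {s}" for s in suffix], dtype=object
        )
        _add(askers, texts, f"term:{term}")

    aware_idx = np.flatnonzero(aware)
    def_texts = np.array(DEFICIENCY_QUERIES, dtype=object)[
        rng.integers(0, len(DEFICIENCY_QUERIES), size=len(aware_idx))
    ]
    _add(aware_idx, def_texts, "b12_deficiency")

    supp_idx = np.flatnonzero(asks_supplement)
    supp_texts = np.array(SUPPLEMENT_QUERIES, dtype=object)[
        rng.integers(0, len(SUPPLEMENT_QUERIES), size=len(supp_idx))
    ]
    _add(supp_idx, supp_texts, "b12_supplement")

    noise_rep = np.repeat(np.arange(n), k_noise)
    noise_texts = np.array(NOISE_QUERIES, dtype=object)[
        rng.integers(0, len(NOISE_QUERIES), size=len(noise_rep))
    ]
    _add(noise_rep, noise_texts, "noise")

    all_user = np.concatenate(ev_user)
    order = np.argsort(all_user, kind="stable")
    all_user = all_user[order]
    events = pd.DataFrame(
        {
            "user_id": user_ids[all_user],
            "text": np.concatenate(ev_text)[order],
            "region": region[all_user],
        }
    )
    truth_events = pd.DataFrame(
        {
            "user_id": user_ids[all_user],
            "kind": np.concatenate(ev_kind)[order],
            "recipe_id": np.concatenate(ev_recipe)[order],
            "region": region[all_user],
        }
    )

    count_cols = [count_column(f) for f in FOODS]
    users_df = pd.DataFrame(
        {
            "user_id": user_ids,
            "region": region,
            "aware": aware,
            "latent_intake": intake,
            "n_recipe_queries": k_recipe,
        }
    )
    expected_df = pd.DataFrame(expected_counts, columns=count_cols)
    expected_df.insert(0, "user_id", user_ids)
    emitted_df = pd.DataFrame(emitted, columns=count_cols)
    emitted_df.insert(0, "user_id", user_ids)
    asks_df = pd.DataFrame(ask, columns=list(terms))
    asks_df.insert(0, "user_id", user_ids)

    truth = GroundTruth(
        users=users_df,
        expected_counts=expected_df,
        emitted_counts=emitted_df,
        events=truth_events,
        term_asks=asks_df,
        term_effects=dict(config.term_effects),
        config=config,
    )
    return events, truth


def generate_regional_expenditure(
    truth: GroundTruth,
    recipes: pd.DataFrame,
    foods: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    category_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Emulate a regional expenditure survey from the true recipe queries.

    Per region the "true" spending fraction of each food category is the
    cost-weighted fraction of recipe queries for foods in that category,
    perturbed by Gaussian noise of sd ``expenditure_noise_sd`` and
    renormalized to a simplex. With zero noise the regional validation
    correlation is 1 by construction.

    Returns a DataFrame with columns ``region``, ``category``, ``fraction``.
    """
    if rng is None:
        rng = _rng(config, 3)
    cmap = category_map or DEFAULT_CATEGORY_MAP
    categories = sorted(set(cmap.values()))
    cost = foods.set_index("food")["unit_cost"]
    m = recipe_incidence(recipes)
    rid_to_row = {rid: i for i, rid in enumerate(recipes["recipe_id"])}

    ev = truth.events
    rec = ev[ev["kind"] == "recipe"]
    out = []
    for region in range(config.n_regions):
        sub = rec[rec["region"] == region]
        if len(sub) == 0:
            logger.warning("region %d has no recipe queries; excluded", region)
            continue
        rows = np.fromiter((rid_to_row[r] for r in sub["recipe_id"]), dtype=int)
        food_counts = m[rows].sum(axis=0).astype(float)
        weighted = {
            cat: sum(
                food_counts[FOODS.index(f)] * cost[f]
                for f, c in cmap.items()
                if c == cat
            )
            for cat in categories
        }
        vec = np.array([weighted[c] for c in categories])
        frac = vec / vec.sum()
        noisy = frac + rng.normal(0.0, config.expenditure_noise_sd, size=len(frac))
        noisy = np.clip(noisy, 0.0, None)
        if noisy.sum() == 0:
            noisy = frac
        noisy = noisy / noisy.sum()
        for cat, value in zip(categories, noisy):
            out.append((region, cat, value))
    return pd.DataFrame(out, columns=["region", "category", "fraction"])


def generate_indications(
    terms: list[str] | tuple[str, ...],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emulate per-drug indication counts from an adverse-reaction database.

    When ``config.indication_params`` is an explicit ``term -> (n, n_pain)``
    map it is passed through. Otherwise counts are drawn under
    :class:`IndicationSettings`: expected indication counts grow with term
    popularity and with the magnitude of the term's negative intake effect,
    and the pain share of indications grows as the effect weakens toward 0
    (coupling off makes all three draws independent of the term parameters).
    """
    if not len(terms):
        raise ValueError("terms must be nonempty")
    params = config.indication_params
    if isinstance(params, dict):
        rows = []
        for term in terms:
            n_ind, n_pain = params[term]
            if not 0 <= n_pain <= n_ind:
                raise ValueError(f"invalid indication counts for {term!r}")
            rows.append((term, int(n_ind), int(n_pain)))
        return pd.DataFrame(rows, columns=["term", "n_indications", "n_pain_indications"])

    settings = params if isinstance(params, IndicationSettings) else IndicationSettings()
    if rng is None:
        rng = _rng(config, 4)

    log_pop = np.array([np.log(config.baseline_term_rates[t]) for t in terms])
    effects = np.array([config.term_effects[t] for t in terms])

    def _z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    if settings.coupled:
        log_mu = (
            np.log(settings.base_n)
            + settings.popularity_coef * _z(log_pop)
            + settings.effect_coef * _z(-effects)
        )
        pain_share = expit(settings.pain_base_logit + settings.pain_effect_coef * _z(effects))
    else:
        log_mu = np.full(len(terms), np.log(settings.base_n))
        pain_share = np.full(len(terms), expit(settings.pain_base_logit))
    n_ind = 1 + rng.poisson(np.exp(log_mu))
    n_pain = rng.binomial(n_ind, pain_share)
    return pd.DataFrame(
        {
            "term": list(terms),
            "n_indications": n_ind,
            "n_pain_indications": n_pain,
        }
    )


def recovery_term_config(
    seed: int,
    n_targets: int = 20,
    n_controls: int = 20,
    effect_scale: float = 0.02,
    baseline_low: float = 0.01,
    baseline_high: float = 0.08,
) -> tuple[dict[str, float], dict[str, float]]:
    """Term maps for recovery studies: negative-effect targets, null controls.

    Target effects are drawn uniformly in ``[-effect_scale, -0.2*effect_scale]``
    mcg^-1 and control effects are exactly 0; baseline ask rates are drawn
    log-uniformly in ``[baseline_low, baseline_high]`` for both sets.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng([seed, 7])
    effects: dict[str, float] = {}
    rates: dict[str, float] = {}
    for i in range(n_targets):
        effects[f"target{i:02d}"] = -effect_scale * rng.uniform(0.2, 1.0)
    for i in range(n_controls):
        effects[f"control{i:02d}"] = 0.0
    for term in effects:
        rates[term] = np.exp(rng.uniform(np.log(baseline_low), np.log(baseline_high)))
    return effects, rates


def coupled_drug_config(
    seed: int,
    n_drugs: int = 40,
    n_users: int = 25_000,
    effect_scale: float = 0.03,
    breadth_coef: float = 0.8,
    pain_coef: float = 0.8,
    effect_noise: float = 0.15,
    **config_kwargs,
) -> SimulationConfig:
    """Config for meta-model studies: drug terms with structured indications.

    Each drug gets two independent exogenous properties - indication breadth
    (lognormal count of conditions it treats) and pain share (logit-normal
    fraction of indications that are pain-related) - and its intake effect is
    built from both: broad-spectrum drugs get a more negative effect (their
    ask signal mixes many conditions) while pain-specific drugs get a weaker
    one. Popularity is coupled positively to breadth. The resulting
    indication counts are stored as explicit ``indication_params`` so
    :func:`generate_indications` reproduces them, and the meta-model's
    indication slope (negative) and pain-indication slope (positive) are
    recoverable by construction.
    """
    rng = np.random.default_rng([seed, 8])
    log_breadth = rng.normal(np.log(25.0), 0.7, n_drugs)
    share_logit = rng.normal(-1.0, 1.0, n_drugs)
    n_ind = 1 + rng.poisson(np.exp(log_breadth))
    n_pain = rng.binomial(n_ind, expit(share_logit))

    def _z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    raw = (
        breadth_coef * _z(np.log(n_ind))
        - pain_coef * _z(share_logit)
        + effect_noise * rng.normal(size=n_drugs)
    )
    effects = -effect_scale * expit(raw)
    log_rate = np.log(0.03) + 0.45 * _z(np.log(n_ind)) + 0.3 * rng.normal(size=n_drugs)
    rates = np.clip(np.exp(log_rate), 0.005, 0.15)
    terms = [f"drug{i:02d}" for i in range(n_drugs)]
    return SimulationConfig(
        seed=seed,
        n_users=n_users,
        term_effects={t: float(e) for t, e in zip(terms, effects)},
        baseline_term_rates={t: float(r) for t, r in zip(terms, rates)},
        indication_params={
            t: (int(ni), int(pi)) for t, ni, pi in zip(terms, n_ind, n_pain)
        },
        **config_kwargs,
    )
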