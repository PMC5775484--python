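"""Turn a raw query-event stream into per-user feature profiles.

Three search classes are recognized: recipe searches (matched against a
recipe corpus by title tokens), medical-term searches (matched against a
target/control lexicon by token-boundary containment) and B12 searches
(keyword classification into deficiency / supplement / serum-level
subtypes). Events are then aggregated into one profile per user: a
12-vector of food search counts, B12-awareness flags and a boolean per
lexicon term, plus the user's modal region.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import FOODS, count_column
from .synthetic import recipe_incidence

logger = logging.getLogger(__name__)

_PUNCT = re.compile(r"[^a-z0-9]+")

DEFICIENCY_WORDS = frozenset({"deficiency", "deficient", "low"})
SUPPLEMENT_WORDS = frozenset(
    {"supplement", "supplements", "pill", "pills", "injection", "injections", "shot", "shots"}
)
LEVEL_WORDS = frozenset({"level", "levels", "test", "serum"})


def tokenize(text: str) -> tuple[str, ...]:
    """Lowercase, strip punctuation, split; merge 'b 12' / 'b-12' into 'b12'."""
    tokens = _PUNCT.sub(" ", text.lower()).split()
    merged: list[str] = []
    i = 0
    while i < len(tokens):
        if tokens[i] == "b" and i + 1 < len(tokens) and tokens[i + 1] == "12":
            merged.append("b12")
            i += 2
        else:
            merged.append(tokens[i])
            i += 1
    return tuple(merged)


# ---------------------------------------------------------------------------
# recipe matching
# ---------------------------------------------------------------------------

class RecipeIndex:
    """Token index over a recipe corpus for order-free title matching.

    A query matches a recipe when either (a) every title token of the recipe
    occurs among the query's tokens, or (b) the query contains the token
    "recipe" together with at least one ingredient name. Among candidates the
    one matching the most title tokens wins, with fewer unmatched title
    tokens preferred on ties (a fully contained title beats a partial
    match); remaining ties break to the smallest recipe_id.
    """

    def __init__(self, recipes: pd.DataFrame):
        self.recipes = recipes.reset_index(drop=True)
        self.ids = self.recipes["recipe_id"].tolist()
        self.title_tokens = [frozenset(tokenize(t)) for t in self.recipes["title"]]
        self.ingredients = [
            frozenset(i.split(";")) for i in self.recipes["ingredients"]
        ]
        self.by_token: dict[str, list[int]] = {}
        for row, toks in enumerate(self.title_tokens):
            for tok in toks:
                self.by_token.setdefault(tok, []).append(row)
        self.by_ingredient: dict[str, list[int]] = {}
        for row, ings in enumerate(self.ingredients):
            for food in ings:
                self.by_ingredient.setdefault(food, []).append(row)
        self.incidence = recipe_incidence(self.recipes)
        self._cache: dict[tuple[str, ...], int | None] = {}

    def row_of(self, recipe_id: str) -> int:
        return self.ids.index(recipe_id)

    def match_tokens(self, tokens: tuple[str, ...]) -> int | None:
        """Return the matching recipe row index, or None."""
        cached = self._cache.get(tokens, -2)
        if cached != -2:
            return cached
        tokset = set(tokens)
        candidates: set[int] = set()
        # (a) full title containment
        for tok in tokset:
            for row in self.by_token.get(tok, ()):
                if self.title_tokens[row] <= tokset:
                    candidates.add(row)
        # (b) "recipe" + >=1 ingredient name
        if "recipe" in tokset:
            for food in tokset & set(FOODS):
                candidates.update(self.by_ingredient.get(food, ()))
        if not candidates:
            result = None
        else:
            result = min(
                candidates,
                key=lambda row: (
                    -len(self.title_tokens[row] & tokset),
                    len(self.title_tokens[row] - tokset),
                    self.ids[row],
                ),
            )
        if len(self._cache) < 500_000:
            self._cache[tokens] = result
        return result


def match_recipe(text: str, index: RecipeIndex) -> str | None:
    """Match a query to a recipe id, or None when no recipe is referenced."""
    row = index.match_tokens(tokenize(text))
    return None if row is None else index.ids[row]


# ---------------------------------------------------------------------------
# B12 and term classification
# ---------------------------------------------------------------------------

def classify_b12_query(text: str) -> dict[str, bool]:
    """Classify a query's B12 content by token keywords.

    ``is_b12`` requires the token "b12" (after normalizing "b-12"/"b 12");
    the deficiency / supplement / level flags additionally require their
    keyword sets and are False whenever ``is_b12`` is.
    """
    tokens = set(tokenize(text))
    is_b12 = "b12" in tokens
    return {
        "is_b12": is_b12,
        "is_deficiency": is_b12 and bool(tokens & DEFICIENCY_WORDS),
        "is_supplement": is_b12 and bool(tokens & SUPPLEMENT_WORDS),
        "is_level": is_b12 and bool(tokens & LEVEL_WORDS),
    }


@dataclass
class TermLexicon:
    """Target and control medical terms, lowercase-normalized and disjoint."""

    target_terms: tuple[str, ...]
    control_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        self.target_terms = tuple(" ".join(tokenize(t)) for t in self.target_terms)
        self.control_terms = tuple(" ".join(tokenize(t)) for t in self.control_terms)
        overlap = set(self.target_terms) & set(self.control_terms)
        if overlap:
            raise ValueError(f"terms in both sets: {sorted(overlap)}")

    @property
    def terms(self) -> tuple[str, ...]:
        return self.target_terms + self.control_terms

    def set_of(self, term: str) -> str:
        return "target" if term in self.target_terms else "control"


def _contains_phrase(tokens: tuple[str, ...], phrase: tuple[str, ...]) -> bool:
    k = len(phrase)
    return any(tokens[i : i + k] == phrase for i in range(len(tokens) - k + 1))


def match_terms(text: str, lexicon: TermLexicon) -> set[str]:
    """Terms whose normalized string occurs contiguously at token boundaries.

    A query may match several terms; when one matched term's token sequence
    is contained in another matched term's, only the longer term is kept
    (longest-match-wins).
    """
    tokens = tokenize(text)
    matched = {
        term
        for term in lexicon.terms
        if _contains_phrase(tokens, tuple(term.split()))
    }
    if len(matched) > 1:
        drop = {
            a
            for a in matched
            for b in matched
            if a != b and _contains_phrase(tuple(b.split()), tuple(a.split()))
        }
        matched -= drop
    return matched


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_users(
    events: pd.DataFrame,
    index: RecipeIndex,
    lexicon: TermLexicon,
    max_repeats_per_recipe: int | None = None,
) -> pd.DataFrame:
    """Aggregate a query-event stream into one profile row per user.

    ``food_counts[i]`` counts the user's events whose matched recipe
    contains food i (a recipe with k ingredients increments k counters);
    term flags and B12 flags are "any event matched"; region is the user's
    modal region (smallest code on ties). Events with empty user ids are
    skipped and counted in a log message. Aggregation is order-independent.

    By default repeated searches for the same recipe each count ("number of
    searches" is per event); ``max_repeats_per_recipe`` caps how many events
    per (user, recipe) pair contribute.

    Returns a DataFrame with columns ``user_id``, ``region``, one
    ``count_<food>`` column per tracked food, ``asked_b12``,
    ``asked_deficiency``, ``asked_supplement``, ``asked_level`` and one
    ``term_<term>`` 0/1 column per lexicon term.
    """
    ev = events.copy()
    ev["user_id"] = ev["user_id"].astype(str)
    bad = (ev["user_id"].str.strip() == "") | ev["user_id"].isin(("nan", "None"))
    if bad.any():
        logger.info("skipping %d events with empty user_id", int(bad.sum()))
        ev = ev[~bad]
    ev = ev.reset_index(drop=True)

    terms = lexicon.terms
    uniq_text, inverse = np.unique(ev["text"].to_numpy(dtype=object), return_inverse=True)

    recipe_row = np.full(len(uniq_text), -1, dtype=int)
    b12_flags = np.zeros((len(uniq_text), 4), dtype=bool)
    term_flags = np.zeros((len(uniq_text), len(terms)), dtype=bool)
    term_pos = {t: i for i, t in enumerate(terms)}
    for i, text in enumerate(uniq_text):
        row = index.match_tokens(tokenize(text))
        if row is not None:
            recipe_row[i] = row
        c = classify_b12_query(text)
        b12_flags[i] = (c["is_b12"], c["is_deficiency"], c["is_supplement"], c["is_level"])
        for term in match_terms(text, lexicon):
            term_flags[i, term_pos[term]] = True

    user_codes, user_ids = pd.factorize(ev["user_id"], sort=True)
    n_users = len(user_ids)

    counts = np.zeros((n_users, len(FOODS)), dtype=np.int64)
    has_recipe = recipe_row[inverse] >= 0
    users_r = user_codes[has_recipe]
    recipes_r = recipe_row[inverse][has_recipe]
    if max_repeats_per_recipe is not None:
        if max_repeats_per_recipe < 1:
            raise ValueError("max_repeats_per_recipe must be >= 1")
        pair_counts = (
            pd.DataFrame({"u": users_r, "r": recipes_r})
            .groupby(["u", "r"])
            .size()
            .clip(upper=max_repeats_per_recipe)
        )
        users_r = pair_counts.index.get_level_values("u").to_numpy()
        recipes_r = pair_counts.index.get_level_values("r").to_numpy()
        contrib = index.incidence[recipes_r].astype(np.int64) * pair_counts.to_numpy()[:, None]
    else:
        contrib = index.incidence[recipes_r].astype(np.int64)
    np.add.at(counts, users_r, contrib)

    flags = np.zeros((n_users, 4), dtype=bool)
    np.logical_or.at(flags, user_codes, b12_flags[inverse])
    tflags = np.zeros((n_users, len(terms)), dtype=bool)
    np.logical_or.at(tflags, user_codes, term_flags[inverse])

    # modal region, smallest code on ties
    region_mode = (
        pd.DataFrame({"u": user_codes, "region": ev["region"].to_numpy()})
        .groupby(["u", "region"])
        .size()
        .reset_index(name="n")
        .sort_values(["u", "n", "region"], ascending=[True, False, True])
        .drop_duplicates("u")
        .set_index("u")["region"]
        .reindex(range(n_users))
        .to_numpy()
    )

    out = pd.DataFrame({"user_id": user_ids, "region": region_mode})
    for j, food in enumerate(FOODS):
        out[count_column(food)] = counts[:, j]
    out["asked_b12"] = flags[:, 0]
    out["asked_deficiency"] = flags[:, 1]
    out["asked_supplement"] = flags[:, 2]
    out["asked_level"] = flags[:, 3]
    for j, term in enumerate(terms):
        out[f"term_{term}"] = tflags[:, j]
    return out


def filter_terms(profiles: pd.DataFrame, min_askers: int = 1000) -> pd.DataFrame:
    """Retain terms asked by at least ``min_askers`` users.

    Returns a DataFrame (``term``, ``n_askers``) sorted by ``n_askers``
    descending (term ascending on ties), containing only retained terms.
    """
    if min_askers < 1:
        raise ValueError("min_askers must be >= 1")
    term_cols = [c for c in profiles.columns if c.startswith("term_")]
    rows = [
        (c[len("term_"):], int(profiles[c].sum()))
        for c in term_cols
    ]
    df = pd.DataFrame(rows, columns=["term", "n_askers"])
    df = df[df["n_askers"] >= min_askers]
    return df.sort_values(
        ["n_askers", "term"], ascending=[False, True]
    ).reset_index(drop=True)
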