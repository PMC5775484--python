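# Methods

This note documents the statistical procedure the package implements, the
synthetic data model it is validated against, and the numerical and design
choices made where the procedure left room.

## The analysis pipeline

The pipeline estimates each search-engine user's dietary vitamin B12 intake
from their recipe searches and asks whether low estimated intake predicts
searching for pain- and neuropsychiatry-related medical terms.

**Consumption score.** Twelve ingredient foods are tracked: shellfish,
mackerel, beef, trout, salmon, tuna, milk, turkey, egg, pork, chicken
(B12 contents 98.9, 19, 6, 3.8, 2.4, 1.6, 0.9, 0.8, 0.6, 0.4, 0.3 mcg per
100 g) and tomatoes (negligible content, treated as 0 — the negative
control). For user *u* with food search counts *x<sub>u,i</sub>* the score
is *s<sub>u</sub> = Σ<sub>i</sub> c<sub>i</sub> x<sub>u,i</sub>*, where
*c<sub>i</sub>* is the content vector. A query contributes to every food
contained in its matched recipe. The score is a relative intake proxy, not
an absolute daily intake: its scale depends on how often a user searches.

**Per-term model (R²I, CoB12).** For every medical term *t*, a linear
probability model is fitted by OLS: the 0/1 indicator "user asked about
*t*" is regressed on the 11 B12-food counts plus an intercept. R²I is the
model's coefficient of determination; CoB12 is the Pearson correlation
between the 11 fitted food coefficients and the content vector. Negative
CoB12 means users who search for B12-rich foods ask about the term less.
Target terms (pain/neuropsychiatric) are compared with control terms via
the ratio of median top-10 R²I values and the rank-sum test on the two
CoB12 samples.

**Consumption-side validations.** (i) Regional validation: per region, the
cost-weighted fraction of recipe queries per food category (6 categories:
beef, pork, poultry, fish/seafood, eggs, milk) is Pearson-correlated with
an expenditure-survey fraction table over all region x category cells.
(ii) Awareness contrasts: mean consumption score of users who asked about
B12 (or specifically B12 deficiency) versus those who did not, with a
two-sided Wilcoxon rank-sum test; the percent difference uses the flagged
group's mean as denominator (this convention reproduces both published
percentages from the published means). (iii) Supplement contingency: the
2x2 of asked-deficiency x asked-supplement, summarized by the ratio of the
two conditional supplement-asking proportions.

**Meta-model.** For drug terms with indication records (total indication
count and count of pain-related indications), CoB12 is modeled as a
function of asker count, indication count and pain-indication count by
*rank regression*: response and predictors are replaced by average ranks,
centered and rescaled to [-1, 1], and the design contains the three main
effects, all pairwise products and the three-way product, fitted by
weighted least squares with weights proportional to R²I (normalized to
mean 1, so equal weights reduce exactly to unweighted rank regression).
Centering the ranks before forming products keeps the interaction columns
near-orthogonal to the main effects; with raw ranks the products are almost
collinear with the main effects and their signs are meaningless. If the
design is still rank-deficient, interactions are dropped three-way first.
Slopes are reported on this centered-rank scale.

## Numerical choices

- OLS is solved by `numpy.linalg.lstsq`; a rank-deficient design yields the
  minimum-norm solution with a logged warning. Agreement with an explicit
  normal-equations solve is tested to 1e-8.
- Rank-sum test: exact null distribution when the smaller group has <= 10
  observations and no ties are present; tie-corrected normal approximation
  otherwise.
- Constant ask vectors (nobody or everybody asked) make R² undefined; such
  terms are skipped with a log message.
- A zero-variance coefficient vector makes CoB12 undefined; NaN is
  returned and excluded from set means.
- Term ranking ties break by asker count (descending), then term label.
- The supplement rate ratio with an empty unexposed numerator is reported
  as infinite with an explicit flag rather than raising.

## The synthetic data generator

The original logs are proprietary, so every input is emulated with recorded
ground truth and recovery is tested against that truth.

Per user: a diet preference over the 12 foods is drawn from a symmetric
Dirichlet (concentration 2 per food by default — substantial between-user
heterogeneity); a Poisson(8) number of recipe queries is emitted, each
picking a food by preference and then a recipe containing it uniformly;
query text is the recipe title plus the token "recipe". Latent intake is
defined as the *expectation* of the consumption score under that
preference, so the generator and the estimator share the content vector by
construction and the estimator is unbiased for latent intake. Each medical
term is asked with probability `expit(logit(baseline) + effect x (intake -
mean intake))` — a logistic ask model, deliberately not the linear model
the analysis fits, so recovery tests also probe robustness to the link. A
small awareness fraction (5.6e-4 by default, matching the observed
deficiency-asker share of the original population) reweights its food
preference by `exp(shift x c_i / max c)` with shift <= -0 (default -2),
always emits a "b12 deficiency" query, and asks about supplements with
probability 3.83e-2 versus 2.53e-4 for everyone else (the two observed
conditional rates). Non-matching noise queries (Poisson(2) per user) give
the matchers something to reject. Regions are integer codes assigned
uniformly.

Expenditure tables are the generator's own cost-weighted regional query
fractions plus Gaussian noise on the simplex (sd 0.05 by default,
renormalized), so zero noise makes the regional validation exactly 1 —
used as an exactness check of the aggregation path.

Indication counts can be passed explicitly, drawn independently, or drawn
coupled: expected indication counts increase with term popularity and with
effect magnitude, and the pain share increases as the effect weakens. For
meta-model sign-recovery studies, `coupled_drug_config` builds the
structure the other way around — indication breadth and pain share are
independent exogenous drug properties and the term's intake effect is a
noisy monotone function of both (more breadth -> more negative effect;
more pain share -> weaker effect). This makes the two partial slopes
separately identifiable; deriving both counts from a single latent effect
makes them collinear and the weaker slope's sign unrecoverable.

What the generator does **not** emulate: query timestamps and sessions,
typos and paraphrase in query text, geographic structure beyond a region
code, and correlation between diet and region. Passing recovery tests
therefore shows the pipeline is correct and calibrated under the stated
generative model, not that the dietary signal exists in real logs.

## Study sizes

Simulation studies use sizes chosen to give the recovery checks stable
power: CoB12 recovery runs 20 seeds of 50,000 users with 20 negative-effect
target terms (effects drawn in [-0.02, -0.004] per mcg; latent intake has
mean ≈ 176 and sd ≈ 39 mcg under the defaults) and 20 null controls; null
calibration runs 100 seeds of 4,000 users with 30 zero-effect terms;
meta-model sign recovery runs 20 seeds of 25,000 users with 40 drug terms.

## Known limitations

- The consumption score has arbitrary scale; only contrasts and
  correlations are interpretable, never absolute intake (matching the
  original design's own limitation).
- The linear probability model's R² values are intrinsically tiny for rare
  outcomes; they are used comparatively (target vs control, term vs term).
- The recipe matcher assumes clean, template-like queries; its >= 95%
  recovery rate is a property of the synthetic templates, not of real
  query noise.
- Weighting by R²I upweights exactly the terms with the strongest fitted
  signal; the meta-model is descriptive, not causal.
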