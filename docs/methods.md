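# Methods

This note documents the statistical procedures implemented in `emospat`,
the defaults and why they were chosen, the design of the synthetic
validation scenarios, and the package's known limitations.

## Emotion scoring

Scoring is dictionary-based. The lexicon follows the common Chinese
affective-ontology annotation scheme: each word carries one of seven
primary emotion classes (joy, like, anger, sadness, fear, disgust,
surprise), a free subcategory tag, an ordinal intensity in {1, 3, 5, 7, 9}
and a polarity. Only polarity × intensity enters the score; the class
columns are carried for bookkeeping. Words tagged `neutral` or `ambiguous`
are excluded from matching (contributing 0 avoids sign errors for
context-dependent words such as "震惊"), though like any non-modifier token
they terminate a modifier run.

**Modifier rule.** For each matched emotion word, the maximal contiguous
run of negation/degree tokens immediately to its left is collected; the
word's contribution is the product of those modifier weights times its
signed intensity. Consequences of the product rule: double negation
restores the sign ((−1)·(−1) = +1); order within a run is irrelevant; a
modifier separated from the emotion word by any other token — including a
previous emotion word — contributes nothing. This strict
contiguous-adjacency reading is a deliberate choice; a looser rule that
scans back to the previous emotion word would change scores only for
sentences with stray tokens inside the modifier window.

**Weights.** Negation defaults to −1. Degree adverbs ship in six strength
classes — most 2.0, very 1.75, more 1.5, over 1.25, slightly 0.75,
insufficiently 0.5 — the conventional strength ordering of Chinese
degree-adverb classes; all weights are file-configurable and no claim is made that any
particular study used these exact values.

**Sentences and posts.** Text splits at terminal punctuation
(。！？!?；; configurable); text without terminal punctuation is one
sentence. A post's score is the sum of its sentence scores (sentence-sum,
not sentence-mean: an additive evidence model, and the only convention
under which score additivity over concatenation holds exactly). Valence is
the sign of the score; exact zero — including posts with no matches — is
neutral. A configurable dead band ε (default 0) can widen the neutral zone.

**Tokenisation** is pluggable (`text -> list[str]`). The default is a
deterministic longest-match segmenter over a protected vocabulary (lexicon
∪ modifiers ∪ user-supplied extra words): vocabulary words are never
split, unknown CJK runs fall back to single characters, non-CJK runs split
on whitespace. This is exact for scoring (which only consumes vocabulary
tokens and run boundaries) and adequate for term tables; a proper
statistical segmenter can be dropped in for natural corpora.

## Stage segmentation

Crisis communication distinguishes an emergency stage (T1), a contagion
stage (T2) and a resolution stage (T3). The package codifies the
qualitative signature — mean emotion below zero early, above zero later,
with a sustained elevated tail — as a sign-persistence rule on the daily
mean score:

- smooth with a centred moving average of `smooth_days` (default 3),
  linearly interpolating zero-post days (which can never start a
  persistence run);
- the T2 onset is the first day from which the smoothed mean is ≥ 0 for
  `persist_days` (default 3) consecutive days;
- the T3 onset is the first later day from which the smoothed mean stays
  ≥ 0 through the window end **and** whose preceding `trailing_days`
  (default 7) of observed means average above the whole-window mean. The
  trailing window deliberately ends the day *before* the candidate: T3
  should begin where the level has already risen, so the evidence for
  elevation must precede the onset.

If either break cannot be placed (all-positive series, too-short window),
the segmenter raises and directs the caller to `manual_breaks`, which
always bypass the rule — segmentation of a single observed crisis is
ultimately a judgement call, and the rule is a reproducible default, not a
verdict. Formal changepoint models are intentionally out of scope.

## Emotion heat and spatial autocorrelation

**Heat.** Per (region, stage), heat is x = ln(1 + n) where n counts
emotion-bearing (non-neutral) posts. The log transform removes the
orders-of-magnitude spread in regional posting volume and leaves
zero-post regions well defined at 0. An alternative transform,
ln(1 + Σ|score|), is available behind a flag; engagement weighting (likes,
comments) is not applied.

**Weights.** Binary k-nearest-neighbour weights on great-circle
(haversine) centroid distance, default k = 9. Rows sum to exactly k; the
matrix is generally asymmetric (k-NN is directed) and deliberately **not**
row-standardised. Distance ties break by region order, so construction is
fully deterministic. k-NN rather than contiguity avoids the
non-connected-region problem (islands) and the large disparity in region
areas.

**Global Moran's I** uses the population-variance convention
S² = Σ(xᵢ−x̄)²/n; with binary weights this makes the two analytic extreme
constructions (isolated like-valued pairs → I = +1, isolated
opposite-valued pairs → I = −1) exact, which the tests assert. Inference
defaults to value permutation over regions: pseudo
p = (1 + #{I_perm ≥ I_obs})/(n_perm + 1) for the one-sided "greater"
alternative (mirrored / folded-and-doubled for "less" / "two-sided"), with
E(I), VAR(I) and hence Z estimated from the replicates. The analytic
randomization moments (E(I) = −1/(n−1) and the standard
permutation-moment variance with the kurtosis correction) are implemented
as the `randomization_analytic` method and are cross-checked against the
permutation moments in the tests.

**Local Moran (LISA).** I_i = (xᵢ−x̄)·Σⱼ w_ij (xⱼ−x̄)/S², same S². The
identity Σᵢ I_i = I·S0 (= n·k·I for k-NN weights) holds algebraically and
is asserted numerically. Inference is by conditional permutation: xᵢ is
held fixed and the remaining n−1 values are randomly reassigned to i's
neighbours (default 999 seeded draws); Zᵢ uses the permutation moments and
pᵢ is a two-sided pseudo p (twice the smaller tail, capped at 1).
Significant regions (pᵢ < α, default 0.05) are typed by the quadrant of
(xᵢ−x̄, spatial lag of deviations): (+,+) HH, (−,−) LL, (+,−) HL, (−,+)
LH; all others NS. A degenerate permutation distribution (sd 0, e.g. a
region exactly at the mean) yields NS with NaN diagnostics. No
multiple-testing correction is applied across regions by default, matching
standard exploratory LISA practice; results for all stages include the
whole-window stage "T" alongside T1–T3.

## Synthetic validation scenarios

The generator produces the structure the analysis assumes, with every
planted quantity recorded as ground truth:

- **Regions:** the packaged 31 province-level centroids (or a jittered
  grid). Coordinates are approximate; only pairwise distances matter.
- **Window & stages:** 70 days from 2022-06-09; planned stages of 10 / 25
  / 35 days, matching the arc of an acute outbreak: a short emergency
  phase, a containment phase, a long tail.
- **Valence mixes:** T1 15/55/30 (pos/neg/neu), T2 45/25/30, T3 60/10/30 —
  negative-dominant early, positive-dominant late, neutral ≈ 30%
  throughout.
- **Volumes:** per-region lognormal base rates (median 2.5 posts/day,
  log-sd 0.35) with stage attention factors 3.0 / 1.0 / 0.4; total corpus
  ≈ 8 000 posts. The log-sd is a validation-design choice: the planted
  cluster effect (ln 3 ≈ 1.1) is set at ≈ 3 residual standard deviations
  so the scenario tests recovery of an identifiable signal rather than the
  power limit of the statistic; real inter-province volume disparities are
  larger, but so are real event effects.
- **Planted cluster:** the outbreak region plus its 7 nearest neighbours
  post at 3× their base rate during T1 and T2 (the hotspot pattern
  collapses in the resolution stage). Recovery is therefore scored in the
  stages where the cluster is planted.
- **Text:** composed from the packaged synthetic lexicon in self-contained
  chunks — an emotion word of the drawn sign, optionally
  degree-intensified, or an opposite-sign word under a single negation —
  plus stage-characteristic topic words, joined by clause commas so chunks
  cannot interact. By construction the score sign of every generated post
  equals its drawn valence, which the tests verify exactly.

What the generator does **not** emulate: natural-language syntax and
word order, sarcasm/irony (the known failure mode of dictionary scoring),
crawl artifacts (duplicates, bots), engagement dynamics, within-day
temporal structure, and epidemic case-count covariates. Passing recovery
tests therefore demonstrates that the *pipeline machinery* is correct and
well calibrated — not that lexicon scoring is accurate on real microblog
prose.

## Numerical choices and problem sizes

- Permutation replicates are generated as row-wise argsorts of uniform
  draws (a uniform random permutation per row), vectorised per test.
- Pseudo p-values use the (1 + m)/(n_perm + 1) convention, never exactly 0.
- Null calibration is checked over 2 000 replicates (n = 31, k = 9,
  999 permutations), where the binomial ±3σ band around the nominal 5%
  level is ±1.5 points; moment checks run at 20 000 permutations.
- Recovery experiments default to 100 seeds in the test suite and 60 in
  the acceptance script; stage-boundary recovery uses 200 planted
  sign-change series. These sizes give stable rates (MC error of a few
  percentage points) at desk-scale runtimes.
- Degenerate inputs fail loudly: zero-variance heat vectors raise, as do
  k ≥ n, unknown region codes, invalid lexicon rows and non-tiling stage
  partitions.

## Limitations

- Dictionary scoring measures expressed surface sentiment; negated-scope,
  irony and domain drift require lexicon curation (the merge/extension
  mechanism exists for that purpose, the curation itself is human work).
- The stage rule presumes the below-zero → above-zero signature; crises
  with different emotional arcs need `manual_breaks`.
- k-NN weights treat centroids as point locations; polygon topology,
  population weighting and distance decay are not modelled.
- LISA p-values are per-region and exploratory; the optional FDR flag
  trades sensitivity for family-wise control.
- The per-category emotion profile (joy vs fear vs anger …) is carried in
  the lexicon but not aggregated by the pipeline; only valence enters the
  spatial analysis.
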