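# emospat

Spatiotemporal analysis of public emotion in geotagged short texts during
sudden public-health crises.

After an acute event (an outbreak, a recall, a disaster), public emotion
expressed on microblogging platforms evolves through recognisable
life-cycle stages and clusters geographically around the event's epicentre.
`emospat` turns a table of geotagged, timestamped posts into a quantitative
account of that process, for researchers in health communication, crisis
informatics and spatial epidemiology:

1. **Lexicon-based emotion scoring.** Each post is cleaned (mentions, URLs,
   repost markers, fillers removed; emoji shortcodes mapped to text),
   segmented with a deterministic longest-match tokenizer over a protected
   vocabulary, and scored by emotion-word matching. An emotion word *e*
   with polarity sign *s(e) ∈ {+1, −1}* and ordinal intensity
   *I(e) ∈ {1,3,5,7,9}* contributes

   *w(e) = (∏ modifiers m in the run immediately left of e) · s(e) · I(e)*,

   where negation words carry weight −1 and degree adverbs multiplicative
   weights (2.0 … 0.5). The post score is the sum over sentences; its sign
   is the post's valence (positive / negative / neutral).

2. **Stage segmentation.** The daily mean score series is smoothed and
   split into the emergency stage **T1** (sub-zero emotion), the contagion
   stage **T2** (emotion fluctuating above zero) and the resolution stage
   **T3** (sustained elevated level), by a reproducible sign-persistence
   rule with a manual override.

3. **Spatial autocorrelation of emotion heat.** Per region *i* and stage,
   emotion heat is *x_i = ln(1 + nᵢ)* with *nᵢ* the count of
   emotion-bearing posts. With binary k-nearest-neighbour weights *w_ij*
   over region centroids (great-circle distance, default *k* = 9):

   - global Moran's **I** = Σᵢ Σ_{j≠i} w_ij (xᵢ−x̄)(xⱼ−x̄) / (S² Σ w_ij),
     S² = Σ(xᵢ−x̄)²/n, tested by value permutation over regions
     (Z = (I − E(I))/√VAR(I), pseudo p-values; analytic randomization
     moments available);
   - local Moran's **I_i** = (xᵢ−x̄) Σⱼ w_ij (xⱼ−x̄) / S² with
     conditional-permutation inference and LISA typing of significant
     regions: HH hotspots, LL coldspots, HL/LH spatial outliers.

4. **Topic tables.** Ranked term frequencies per stage and per region —
   the substrate of word clouds.

5. **Synthetic scenarios with ground truth.** A generator that plants
   stage-dependent valence mixes, heavy-tailed regional volumes and a
   high-rate spatial cluster around an outbreak region, so every step above
   can be validated by parameter recovery — no proprietary corpus needed.

## Worked example

```python
import emospat as es

scenario = es.make_scenario(seed=42)        # 31 provinces, 70 days, planted cluster
posts, truth = es.generate_posts(scenario)  # ~8k posts with ground truth
model = es.EmotionSpatialModel(posts.drop(columns=["true_valence"]))
results = model.fit(k=9, n_perm=999, seed=42)
print(results.summary())
```

```
Spatiotemporal public-emotion analysis
======================================================
posts: 8259   regions: 31   k-NN: 9   permutations: 999   seed: 42

Stage partition
------------------------------------------------------
  T1: 2022-06-09 .. 2022-06-19   pos 16.4%  neg 53.4%  neu 30.1%  (n=3957)
  T2: 2022-06-20 .. 2022-07-17   pos 45.1%  neg 25.5%  neu 29.4%  (n=3228)
  T3: 2022-07-18 .. 2022-08-17   pos 56.8%  neg 11.0%  neu 32.2%  (n=1074)

Global Moran's I (emotion heat, permutation test)
------------------------------------------------------
  stage        I     E(I)       Z       p
  T        0.338  -0.0332   5.996   0.001
  T1       0.357  -0.0348   6.330   0.001
  T2       0.359  -0.0344   6.270   0.001
  T3      -0.071  -0.0346  -0.579   0.693

LISA cluster counts
------------------------------------------------------
      HH  LL  HL  LH  NS
  T    8   4   1   1  17
  T1   7   5   1   2  16
  T2   7   4   1   2  17
  T3   0   1   0   0  30
```

Reading it: the segmentation recovers the planted emergency window
(negative-dominant, 53% negative posts), emotion turns positive through the
contagion and resolution stages, and emotion heat is strongly spatially
clustered while the planted high-rate cluster is active (I ≈ 0.36,
p = 0.001 in T1/T2) with 7 of the 31 regions flagged as HH hotspots —
the planted 8-region cluster around the outbreak province — before
clustering collapses in T3, where the cluster is no longer active.
`es.evaluate_recovery(truth, results.partition, results.local_moran["T1"],
results.global_moran["T1"])` scores this against the ground truth
(here: boundary error 1 day, HH sensitivity 0.75, specificity 0.96).

The same analysis runs from the shell:

```bash
emospat simulate --seed 42 -o sim/
emospat run --posts sim/posts.csv -k 9 --perm 999 --seed 42 -o out/
```

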