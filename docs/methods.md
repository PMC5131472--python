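# Methods

## Model and assumptions

`netweights` predicts edge weights in an undirected weighted network
G(V, E, W) under a local-homogeneity assumption: weight formation is
regulated by local clusterings, so links embedded in the same neighborhood
tend to carry related weights. The operational form is an independence
(product) hypothesis — if the events "α interacts with x" and "α interacts
with y" are independent, the interaction strength of (x, y) is
approximately the product `w_αx · w_αy` — corrected by the empirical
deviation of the neighborhood from that rule.

For a candidate pair (x, y):

- **Within-set evidence**, one item per common neighbor α
  (x, y ∈ Γ(α)):

      R_α = (1 + Σ_{(i,j)∈E, i,j∈Γ(α)} w_ij / (w_αi · w_αj)) / (1 + m_α)
      estimate = w_αx · w_αy · R_α
      probability = m_α / C(|Γ(α)|, 2)        (local clustering coefficient)

  with m_α the number of links inside Γ(α). The `1 + …` add-one smoothing
  keeps R defined when m_α = 0 and makes the empty-neighborhood limit the
  pure product rule.

- **Cross-set evidence**, one item per unordered center pair {α, β} with
  α ∈ Γ(x)\{y}, β ∈ Γ(y)\{x}, α ≠ β (common neighbors may also appear
  inside cross pairs). The ratio sum runs over existing links (i, j) with
  i ∈ Γ(α), j ∈ Γ(β), i ≠ j, each unordered link counted once; the
  probability is the number of such links over the number of distinct
  unordered pairs spanning Γ(α) and Γ(β), computed by inclusion–exclusion
  over the shared members (self-pairs excluded).

- **Combination**: all probabilities are normalized to sum to one and the
  prediction is the probability-weighted mean of the estimates. With no
  evidence, or all probabilities zero, the prediction is 0 — the same
  convention the evaluation uses for non-observed links.

**Orientation symmetry.** The cross-set quantities must not depend on
which endpoint contributed which center. A cross link that qualifies in
both orientations (both endpoints in both neighborhoods) contributes the
mean of its two orientation ratios, once; likewise the estimate prefactor
`w_xα · w_yβ` is averaged over the valid orientations of the unordered
pair {α, β}. This makes `predict_weight(x, y) = predict_weight(y, x)`
exactly, which the suite asserts.

**Target exclusion.** The candidate pair is excluded from every ratio sum
and density count, even when the pair is an existing edge. Hence
predicting the hidden weight of a known link uses exactly the information
a case-2 evaluation is allowed to see; the suite verifies that predicting
over an existing edge equals predicting after deleting it.

## Similarity indices

Nine local indices rank candidate links before weight prediction, with
Z = Γ(x) ∩ Γ(y), k_z the degree, s_z the strength, natural logarithms:

| family | unweighted | weighted | reliable-route |
|---|---|---|---|
| CN | \|Z\| | Σ (w_xz + w_zy)/2 | Σ w_xz·w_zy |
| AA | Σ 1/log k_z | Σ (w_xz + w_zy)/(2 log(1+s_z)) | Σ w_xz·w_zy / log(1+s_z) |
| RA | Σ 1/k_z | Σ (w_xz + w_zy)/(2 s_z) | Σ w_xz·w_zy / s_z |

Only distance-2 pairs are materialized (all nine indices vanish beyond
two hops), keeping candidate scoring at O(Σ_z k_z²). Ties in the top-L
ranking break lexicographically, and when fewer than L pairs carry a
score the list is padded with zero-score candidates in lexicographic
order so |E^L| = L always holds. On all-unit-weight graphs WCN and rWCN
reduce to CN and WRA/rWRA to RA; WAA/rWAA do **not** reduce to AA because
log(1+s_z) ≠ log k_z at unit weights.

## Linear-correlation baseline

The comparison method predicts ŵ = λ·s with
λ = (Σ sᵢwᵢ)/(Σ sᵢ²), the closed-form minimizer of ‖λS − W‖. By
construction it fits λ against the validation weights themselves, so
validation information leaks into its optimization and its accuracy is
optimistically biased; the implementation reproduces this deliberately
for comparability and logs a warning whenever the baseline runs.

## Evaluation protocol

Edges are split uniformly at random into E^T (fraction f, rounded
half-away-from-zero) and E^V; the training graph keeps all nodes.
Weights are normalized once globally (divide by the maximum) before
splitting; a strict `normalize="train"` mode that uses only the training
maximum is available for leakage-free workflows. Case 1 ranks candidates
of the training graph with a chosen index, takes the top L = |E^V| pairs,
predicts their weights, and scores against actual weights that are the
true weight for validation pairs and 0 otherwise. Case 2 sets E^L = E^V
directly. Accuracy is Pearson r and RMSE per repetition, averaged;
repetitions with a zero-variance vector have no defined r and are flagged
and excluded from the Pearson mean rather than recorded as 0, which would
bias the average. A master seed spawns per-repetition (and per-fraction)
seeds through `numpy.random.SeedSequence`, so reports are bitwise
reproducible and extending `reps` never changes earlier repetitions.

## Synthetic generator

The generator realizes the method's own assumption so recovery can be
measured against ground truth: node affinities a_v ~ Uniform(0.2, 1.0),
edges from a community block model (p_in/p_out; a single community — the
default — is a plain random graph), and weights
`w_uv = a_u · a_v · exp(σ·z_uv)` with standard-normal z, then
max-normalized. Noise is multiplicative so weights stay positive. The
defaults (n = 60, edge density 0.3, σ = 0) are the study conditions used
by the test harness; they give ≈ 500 edges, large enough for stable
statistics and small enough that the full protocol runs in seconds. The
noise draw is consumed even at σ = 0 so a fixed seed yields the same
topology at every noise level.

What the generator does *not* emulate: heavy-tailed degree distributions,
degree–weight correlations, and weights that are not similarity-like
(e.g. trophic flows) — all present in real networks. Passing recovery
tests therefore shows the estimator is correct *under its own model*, not
that it attains any particular accuracy on empirical data; on real
networks accuracy depends on how closely weights factorize locally.

## Numerical choices

- All evidence sums run in lexicographic node-label order; predictions
  are deterministic to the bit, and the brute-force equivalence test
  checks the engine against a direct-definition enumeration at 1e-12.
- Per-center internal-link terms and per-center-pair cross terms are
  memoized per training graph; exclusion of the candidate pair is applied
  at summation time, so caching cannot change results (asserted).
- Scale behaviour: with no observed ratio links (m = 0) the estimates
  scale exactly as c² when all weights are scaled by c, by the product
  rule. In the smoothed regime (m > 0) the `1 + Σ` numerator breaks exact
  scale equivariance — the smoothing constant is on the scale of ratio 1,
  i.e. of perfectly multiplicative weights.
- Zero or negative input weights are errors, never silently dropped: zero
  is the sentinel for "non-observed link" in the evaluation.
- Pajek `*Arcs` entries are symmetrized by summing the two directed
  weights (natural for flight-count data); `max` and `mean` are options.

## Open design points, as resolved here

- Cross-pair enumeration takes the broadest reading: every unordered pair
  of centers drawn from the two (endpoint-stripped) neighborhoods,
  counted once, with common neighbors eligible on both sides.
- The cross-density denominator counts distinct unordered spanning pairs
  (11 on the toy graph, not 12): ordered or self-pair counting would
  double- or phantom-count evidence.
- Normalization happens once globally before splitting by default, since
  per-split renormalization changes the target scale between repetitions;
  the train-only mode exists for strict no-leakage studies.

## Known limitations

- Case-1 accuracy is bounded by link-prediction precision: if the top-L
  candidates rarely coincide with the validation edges — as on unclustered
  random topologies — the actual-weight vector is mostly zeros and r is
  low regardless of the weight predictor's quality. The case-1 tests
  therefore use a clustered generator (5 communities, p_in = 1.0,
  p_out = 0.05) where the link-prediction step is feasible.
- Evidence is strictly 2-hop; nodes whose neighborhoods carry no internal
  or spanning links fall back to smoothed products, and fully isolated
  pairs predict 0.
- Complexity is O(k²) per candidate pair in neighborhood size; dense
  graphs with large hubs are the slow case (memoization amortizes this
  across pairs sharing centers).
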