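# Methods

This note documents the models and procedures implemented in `combisyn`,
the assumptions behind the synthetic screen, the defaults that matter, and
the limits of what the synthetic validation can show about real data.

## Synergy scale and labelling

Combinations are summarised by a dimensionless synergy score γ with
baseline 1 (no interaction), lower values indicating synergy. The binary
label is γ < 0.95, with the boundary value classified non-synergistic;
γ < 0.5 is flagged "strong". The package treats γ as a measured response
surface summary and does not re-derive it from matrices: the generator
produces γ directly from a mechanistic model (below) and produces matrices
*consistent with* it, embedding an excess-Bliss inhibition of
κ·(1 − γ) with κ = 0.25 on nonzero-dose cells. Excess-surface summaries
therefore correlate monotonically with γ, but no exact functional
correspondence between the two is claimed, and none is relied on.

## Assay geometry

Each 10×10 block has dose index 0 as vehicle and indices 1–9 as nine 1:2
serial dilutions; dose k is IC50·2^(k−5.5), which places each compound's
IC50 at the geometric mean of doses 5 and 6 ("roughly mid-range") and spans
a 256-fold range. Single agents follow a Hill curve with slope 1 and a
maximal effect E_max = 0.7 by default. E_max = 0.7 keeps the Bliss
composition plus the κ·(1 − γ) excess inside the [0, 1] response range for
γ ≥ 0.5, so the mean excess of a noiseless block equals κ·(1 − γ) exactly
rather than being flattened by clipping; it is also consistent with an
activity filter requiring at least 50% efficacy. Responses are fractional
inhibition (0 = vehicle, 1 = no-cells control); raw signal normalisation
is out of scope.

## The synthetic screen and its ground truth

The generator emulates an annotated oncology screening library:

| parameter | default | rationale |
|---|---|---|
| library size | 1785 | screen scale being emulated |
| active compounds | 32 | single-agent hit count |
| MoA vocabulary | 821 labels | annotation vocabulary size |
| log10 IC50 of actives | uniform in [−8.7, −5.5] | observed potency range (≈2 nM–3 µM) |
| MoA labels per compound | 1–2 (second with p = 0.3) | "diverse and redundant" annotations with small per-pair cross-products |
| active MoA vocabulary | 8 labels | actives concentrate in few mechanisms, so mechanisms recur across compounds |
| replicates | 2 | duplicate blocks |

Ground truth is mechanistic: seven unordered MoA-label pairs (e.g.
proteasome–HDAC inhibition) carry additive effects between −0.25 and −0.45
on the γ baseline of 1.0. Per-pair noise has two components: a shared
"compound-pair" term (sd 0.05) identical across replicates, and independent
replicate noise (default sd 0.07, or calibrated). γ is clipped to [0, 2].

Two aggregate properties of the emulated study pin the noise scales: the
duplicate Pearson correlation (~0.83) and the synergistic fraction of the
training screen (~52%). `calibrate_noise` bisects the replicate noise sd
against simulated screens until the duplicate correlation is within
tolerance of the target; the default effect set and noise sds put the
synergistic fraction at 0.49–0.53 across seeds.

Structures come from a bundled list of 40 drug-like scaffolds, suffixed
with short alkyl/alcohol decorations, and are keyed to the compound's
primary MoA label. This encodes the realistic property that compounds
sharing a mechanism are structurally related — which is precisely what
allows structure-only models to learn mechanism-driven synergy. It is also
the synthetic screen's strongest idealisation (see Limitations).

## Featurization

Per-compound descriptors: Morgan (radius 2) and Avalon fingerprints at 1024
or 2048 bits, and the RDKit physicochemical descriptor battery (names
recorded in `PHYSCHEM_NAMES`). The registry accepts external per-compound
descriptor tables from CSV so families computed elsewhere can be plugged in
without touching callers. Pair features are element-wise averages or sums
(order-invariant); the MoA pair vector is a binary presence/absence vector
over the vocabulary with set semantics (a label shared by both compounds
contributes a single 1); log IC50 values are appended in canonical id
order so the feature vector is independent of argument order. Mixture
graphs are the direct sum of the two adjacency matrices with stacked
per-atom features, blocks in canonical id order.

## Learners and consensus

The default consensus is random-forest classification (on the binary
label) averaged with random-forest regression (on γ) converted to
pseudo-probabilities — min-max scaled over the prediction batch being
converted and flipped, so the lowest predicted γ maps to score 1. Batch
scope for the scaling is a documented choice; it preserves ranking exactly
(Spearman −1 against the raw predictions), which is what the consensus
consumes. Majority voting is provided as a secondary rule; even splits
vote synergistic, a documented tie-break.

Forests use 50 trees by default: with ~500 training pairs the
cross-validated AUC plateaus well below this size, and the smaller default
keeps repeated-seed validation experiments cheap. Gradient boosting
(learning rate 0.01) and a 700/500/300 feed-forward network (Adam, learning
rate 1e-4, batch 128, 70 epochs) are available through `LearnerSpec` for
benchmarking but are not in the default consensus.

## The Bliss-residual surrogate

`SurrogateComboModel` is a small multi-task network written directly on
numpy: a shared molecule encoder feeds a single-agent head s(·) and a
combination head c(·,·) computed from the symmetric sum of the two hidden
vectors, both sigmoid-squashed. Synergy is scored as
c(AB) − [s(A) + s(B) − s(A)s(B)] ∈ [−1, 1]. Training is full-batch Adam on
the joint MSE of the two tasks (400 epochs, learning rate 0.01, hidden
width 64), deterministic under a fixed seed. Two encoders are provided:
`fingerprint_mlp` (Morgan-1024 bits into a trainable hidden layer; the
default) and `graph_conv` (a fixed, seeded random-weight message-passing
embedding with sum pooling feeding the same trainable heads — a
random-features graph encoder appropriate at this data scale).

Training targets come from the screen itself: the single-agent target is
each compound's Hill inhibition at its mid-grid dose; the combination
target is the Bliss composition of those margins plus κ·(1 − γ̄), i.e. the
matched-dose cell of the simulated block. Evaluation uses a seeded 80/10/10
split of the combinations with ROC AUC of the residual score against the
γ < 0.95 label.

## Validation schemes and metrics

One-compound-out: one fold per compound, validation = all pairs containing
it; every pair appears in exactly two validation sets, and per-fold
exclusion properties are re-checked by brute force in the tests.
Everything-out: compounds are partitioned into seeded groups; validation
pairs lie fully inside a group, training pairs fully outside it, and
straddling pairs are dropped from that fold. Y-randomization permutes the
full response (replicates, mean, label) across pairs.

Metrics: sensitivity, specificity, PPV, NPV, balanced accuracy (reported
as CCR — the two terms are used synonymously here), rank-based
(Mann–Whitney) ROC AUC with averaged ties, and hit rate. Ratios with zero
denominators are NaN, never 0. Table-style output rounds half away from
zero to two decimals.

## Nomination strategies

* `topk_nomination` — k highest scores, ties broken by canonical key order.
* `tiered_nomination` — three mutually exclusive tiers with quotas 12/12/6:
  (1) consensus score > 0.7, both compounds active, exactly one in
  training, MoA pair among the selected synergistic pairs; (2) highest
  descriptor-only scores with one training compound and a non-selected MoA
  pair; (3) highest consensus scores with no training compound and a
  selected MoA pair. Shortfalls shrink the list with a warning and are
  never backfilled across tiers, keeping quotas exact and tiers disjoint.
  Synergistic MoA pairs are those with ≥3 training drug pairs and mean
  label ≥ 0.66, computed on primary labels.
* `diversity_capped_topk` — greedy descent through the score ranking,
  skipping pairs that would push either compound past 5 appearances.

"Active" for nomination filters is the `is_active` input flag. The default
library flags exactly the training actives; the pipeline's default config
additionally marks 150 non-training compounds active (`n_extra_active`) so
tier filters requiring active non-training compounds are exercisable.

## MoA network and permutation test

Synergistic records (γ̄ below cutoff; 0.95 and 0.5 both reported)
contribute their cross-compound MoA label pairs as edges, counted over the
full label cross-product (a record adds |moa(A)|·|moa(B)| edge increments;
a `primary_only` switch restricts to primary labels). The null resamples
the observed number of combinations as distinct unordered pairs, uniformly
without replacement within each replicate, from the pool of compounds
appearing in synergistic combinations, and recounts each edge.

Significance is reported two ways. The add-one permutation estimate
(1 + #{null ≥ obs})/(1 + reps) is the primary, assumption-free p-value.
A one-sided normal approximation from the null's mean and standard
deviation is reported alongside, matching the inference implied by a
mean ± SE summary of a permutation null. The distinction matters: under a
uniform-pair null the edge count is exactly hypergeometric, and for a null
mean near 4.4 an observed count of 9 has an exact right tail of ~0.02 —
significant at 0.01 only under the normal approximation (z ≈ 2.5,
p ≈ 0.006). Both numbers are computed and reported so the user can choose
the stricter one.

## Pipeline and determinism

`run_pipeline` executes simulate → featurize → cross-validate → fit → score
a seeded subsample of the virtual library (default 20,000 of ~1.59M pairs;
scoring the full library is linear and possible but unnecessary for
validation) → nominate (all three strategies) → evaluate hit rates against
the generator's noiseless truth labels → network analysis. All randomness
derives from one root seed split per stage; the manifest records the seed,
a config hash and library versions, and equal configs reproduce equal
outputs bit-for-bit. Stage failures abort with the stage name; partial
outputs are retained.

## Numerical and edge-case choices

* γ exactly 0.95 → non-synergistic; self-pairs rejected with a distinct
  error; pair keys canonicalised lexicographically at construction.
* Min-max pseudo-probability conversion raises on an all-equal batch.
* Calibration raises when the screen's γ values carry no shared variance
  (correlation undefined) and brackets the noise sd by doubling before
  bisecting.
* Matrix simulation adds no noise to the vehicle cell, which is exactly 0.
* Sampling of virtual pairs and permutation draws uses numpy Generator
  streams spawned from the root seed; derived seeds stay below 2^31.

## Limitations

* MoA labels drive the ground truth and structures are scaffold-keyed to
  MoA. Real structure–mechanism relationships are far noisier; passing
  synthetic validation shows the machinery is correct and that models can
  recover mechanism-level signal when it exists, not that comparable AUCs
  or hit rates will be obtained on any real screen.
* γ is generated, not derived from the matrices; analyses that depend on
  the exact response-surface definition of γ are out of scope.
* Single-agent curves share slope and E_max across compounds; only potency
  varies. Curve-class heterogeneity, edge effects and plate artefacts are
  not modelled.
* The permutation null treats all pairs as exchangeable; carrier-frequency
  structure beyond label counts (e.g. potency-correlated sampling) is not
  modelled.
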