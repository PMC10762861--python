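# Methods

## Problem and model

`protolink` links mentions in biomedical text to KB concepts in two stages:
candidate retrieval against a synonym dictionary, then re-ranking by a dual
encoder trained with metric learning. The package's focus is the training
objective for imbalanced data: a prototype-based triplet loss over
per-document co-reference clusters, refined by soft-radius neighbor (SRN)
clustering with a learnable radius, with online hardest-negative mining from
the frozen retrieval candidates.

### Retrieval

The synonym dictionary maps each lowercased synonym string to the set of
entities it may denote. Two sparse representations are fitted on the KB
synonyms: character n-grams with n ∈ {2..5}, and word unigrams (tokens split
on any non-alphanumeric character, a fixed built-in English stop-word list
removed). The tf-idf variant is pinned for reproducibility: raw term counts,
smoothed idf `ln((1+N)/(1+df)) + 1`, L2-normalized rows — so cosine
similarity is a dot product. Candidate lists are built by walking synonyms
in non-increasing score order and appending their entities (ties between
synonyms break on the string, entities of one synonym append in
lexicographic ID order) until k distinct entities are collected; per-source
lists merge round-robin starting from the character-n-gram list, keeping
first occurrences, truncated to k (default k = 64). Dense retrieval encodes
bare synonym strings (inputs truncated to 50 encoder tokens) into an exact
exhaustive cosine index; it satisfies the same iterate-until-k contract.

### Re-ranking and losses

Mention inputs follow `[CLS] c_l [START] m [END] c_r [SEP]` (representation:
mean of the `[START]` and `[END]` output rows); entity inputs follow
`[CLS] type [SEP] syn1 [SEP] syn2 [SEP] …` (representation: `[CLS]` row).
Linking sorts candidates by Euclidean distance to the mention embedding,
ties broken by lexicographic entity ID; entity embeddings are computed once
per distinct entity and cached.

The standard triplet loss uses squared Euclidean distances; the
prototype-based loss uses unsquared distances, anchored at the arithmetic
mean of the cluster members' embeddings. The two conventions are kept as
printed in the respective hinge definitions; a `squared_prototype_loss`
switch makes the prototype loss use squared distances for users who prefer a
single convention. The margin α defaults to 1.2.

SRN clustering: given an anchor mention (chosen uniformly at random among
the entity's mentions in the document), every co-referent mention whose
embedding lies strictly within λ + ϵ of the anchor joins the cluster.
Defaults: λ₀ = 11.0, ϵ = 1.0 (additive slack; treating ϵ as a Gaussian
standard deviation around λ was considered and rejected as
under-determined), λ learning rate 0.005. The observed radius of a cluster
is the maximum anchor-to-member distance among included members (0 for a
singleton) — the natural covering radius. λ is updated per batch by an
exponential moving average toward the mean observed radius,
`λ ← λ + lr·(mean(r) − λ)`, clipped at 0; an empty batch leaves λ unchanged.
Each update contracts the gap to a constant target by (1 − lr), so from
λ₀ = 11 the threshold approaches the data's distance scale geometrically.

Hardest-negative mining measures distance from the prototype (the quantity
the loss optimizes); a configuration switch measures from the anchor mention
instead. Negatives come from the mention's precomputed candidate list minus
the gold entity; a cluster with no usable negative is skipped and counted.
The gold entity is always embedded from its KB record, whether or not
retrieval recovered it.

### Training regimes

* `triplet_all` — one loss term per mention.
* `triplet_downsample` — per document, one randomly kept mention per class.
* `proto` — one term per class (document-level cluster = whole class).
* `proto_srn` — one term per SRN cluster around a random anchor.

Batches count clusters (default 32). The optimizer is Adam. Per-epoch loss
evaluation counts follow the regimes exactly: Σ_docs #classes for the
prototype regimes and down-sampling, Σ_docs #mentions for `triplet_all` —
the computational saving claimed for prototype training.

## The toy encoder

The transformer backend is a contract only; the shipped encoder is a
deterministic CPU-scale stand-in designed so that (a) the templates'
extracted rows genuinely summarize the relevant content and (b) training is
exercisable end-to-end:

* Each token maps to a fixed feature vector: hashed character 2/3-gram
  counts (4096 buckets, CRC32 hashing), L2-normalized, passed through a
  seeded Gaussian random projection to d dimensions (default d = 32). Both
  dual encoders share this feature space, as dual BERT encoders share their
  pre-trained initialization.
* Content-token rows are their feature vectors. Special-token rows are
  pooled summaries, mirroring how a transformer's special-token outputs
  summarize context rather than the marker string: `[END]`/`[SEP]` carry the
  mean vector of the segment they terminate, `[START]` carries the mention
  segment plus 0.5× the left context, and `[CLS]` carries the mean over all
  content tokens. A purely token-local encoder would give every mention the
  same marker rows and every entity the same `[CLS]` row, making the
  extracted representations constant and the task unlearnable, so the pooled
  design is load-bearing, not cosmetic. One consequence: permuting
  fully-retained synonyms does not change the entity embedding (mean
  pooling); order matters only through length truncation.
* A trainable d×d head W (initialized to the identity) sits on each encoder.
  Embeddings are linear in W, so the triplet-hinge gradients are closed form
  (`∂‖z‖/∂W_m = ẑ pᵀ` with `z = W_m p − W_e v` and ẑ the unit vector, `2z`
  for squared distances) and training needs no autodiff framework. Training
  therefore updates the metric over the fixed feature space — linear metric
  learning — which is exactly the part of the problem the losses differ on.

Over-length handling: mention context tokens are trimmed alternately from
the far ends (never the mention; both sides lose equally ±1); entity inputs
drop whole trailing synonyms. Maximum input length 128 tokens.

Desk-scale training defaults (`TrainingConfig.desk_scale()`): Adam at
1e-3 for 5 epochs. The 1e-5 default of `TrainingConfig` is the appropriate
order for fine-tuning a transformer backend but is far below the parameter
scale of a 32×32 linear head; 1e-3 was chosen as the largest rate at which
held-out accuracy improves monotonically-ish rather than oscillating.

## Synthetic data

The generator emulates the statistics the method targets:

* **Imbalance** — per-entity mention counts are 1 + Geometric(p = 0.3)
  capped at 50 (mode 2–3, most mass below 10), plus a 5% share of heavy
  entities drawing 20–50 mentions. Each entity places its mentions in one or
  two home documents, so documents contain multi-mention classes — the
  situation prototype clustering exploits — and per-document down-sampling
  discards a large share of mentions (>30% under defaults).
* **Ambiguity** — 10% of synonym strings are also injected into a second
  entity's synonym list.
* **Surface diversity** — mention surfaces are KB synonyms with per-character
  substitute/insert/delete edits at rate 0.05.
* **Context signal** — filler sentences come from a small template bank that
  places the entity's semantic-type word near the mention, so context
  carries a weak, learnable disambiguation signal.
* Synonyms are pronounceable consonant-vowel strings, 1–4 per entity
  (UMLS ≈ 2.2 and MeSH ≈ 2.7 synonyms per entity on average).
* Defaults: 200 entities, 250 documents — small documents keep the
  document-level split granular.

The train/dev/test split partitions documents 60/20/20 at random, then
greedily moves documents between train and dev/test until the fraction of
distinct dev/test gold entities absent from train matches (1 −
seen_fraction) within one entity. Default seen_fraction 0.7.

What the generator does **not** emulate: real lexical morphology and
abbreviations, document discourse, semantic-type ontologies, and
context–entity correlations beyond the type word. Passing tests show the
machinery is correct and that the regime ordering (prototype+SRN ≥ plain
triplet under imbalance) emerges on data with the targeted statistics; they
do not certify accuracy levels on real corpora, which depend on pre-trained
encoders and real surface-form distributions.

## Numerical and design notes

* All randomness (KB and corpus generation, splits, anchor choice,
  down-sampling, batch shuffling, encoder projections) flows from explicit
  seeds; the full pipeline is byte-identical across runs at a fixed seed.
* Cluster membership uses strict inequality at the threshold.
* Distance ties at inference and in mining break on lexicographic entity ID,
  making rankings total orders independent of input order.
* Mentions with empty candidate lists are unlinkable and scored incorrect;
  mentions whose gold entity is missing from candidates count as errors.
* McNemar's comparison uses the chi-square form with continuity correction
  (via statsmodels); zero discordant pairs returns p = 1 by convention.
* At desk scale the initial λ₀ = 11 exceeds typical toy-encoder distances,
  so early SRN clusters equal whole classes and λ contracts toward the data
  scale during training; with a transformer backend (embedding norms an
  order of magnitude larger) the threshold is discriminative from the start.

## Limitations

* The trainable part of the shipped encoder is linear; it cannot learn
  context-dependent disambiguation beyond linear reweighting of the feature
  space. The contract accepts transformer backends, but none is bundled.
* Abbreviation expansion and sentence splitting are assumed applied
  upstream; the corpus reader consumes the text it is given.
* Anchor mentions are chosen uniformly at random; choosing anchors near the
  class centroid is a known refinement left out deliberately.
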