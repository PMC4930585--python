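# Methods

## Models and procedure

### Leave-one-out similarity scoring

The drug–target predictor assumes that binding propensity is carried by
chemical similarity: for candidate drug *D* and target *T*,

    score(D, T) = max over D' in binders(T) \ {D} of S(D, D'),

with the argmax kept as the origin drug. Three consequences of this
definition matter:

* The candidate is always excluded from the binder set, for known pairs
  and unknowns alike. This is the only reading under which known pairs
  receive non-degenerate scores and a global ROC over all combinations is
  meaningful. A known pair can still score 1, but only through a distinct
  binder with similarity exactly 1.
* A target whose only binder is the candidate itself yields an NA score.
  NA candidates are excluded from ranking and evaluation rather than
  scored 0; the minimum-support filter makes them rare, and a 0 would
  deflate enrichment denominators for no informational gain.
* Ties in the maximum are broken by lexicographic drug id, so output is
  deterministic.

`score_all` produces the exact |drugs| × |targets| cross-product (drugs
taken from the similarity matrix, targets from the association table),
sorted by (drug, target).

### Similarity inputs

The package is agnostic about where the similarity matrix comes from.
Two supported routes:

* **3D pharmacophoric overlap volumes.** `normalize_overlap` maps a raw
  pair overlap and the two self-overlaps to
  `O(A,B) / max(O(A,A), O(B,B))` ∈ [0, 1]. Conformer generation and shape
  alignment are deliberately out of scope — any external engine's overlap
  volumes can be normalized and assembled into a matrix.
* **2D fingerprints.** `matrix_from_fingerprints` builds a pairwise
  Tanimoto matrix from any fixed-length binary fingerprints; a MACCS
  backend is provided behind an optional rdkit extra.

Pairwise alignment scores need not be symmetric; `read_similarity_matrix`
symmetrizes with a policy (`max` by default, `mean`, or `strict` refusal)
and forces a unit diagonal. Values outside [0, 1] beyond 1e-9 are
rejected rather than clipped.

### Reference-standard construction

Raw bioactivity records are reduced to a binary edge set by: dropping
records whose assay comment matches a configurable excluded-label set
("not determined", "not active", "not tested", "no inhibition",
"potential missing data"; case-insensitive); dropping threshold-only
potencies (relation `>` or `>=`, which carry no usable number, whatever
the value); dropping potencies above the cutoff (default 50 µM — the
conventional boundary between pharmacologically meaningful and incidental
binding); then collapsing repeated assays of a (drug, target) pair to one
edge, keeping the lowest-potency assay's details as representative
metadata. Records with relation `<` and a value within the cutoff are
kept. The filter is idempotent by construction.

The minimum-support filter removes targets or ADEs with fewer than 5
distinct drugs. It is **single-pass**: degrees are measured once on the
input table and the filter is not iterated after removals, matching
one-shot dataset construction. Consequently a drug may lose all its edges
without triggering re-filtering of the entities it supported.

### Target–ADE enrichment

For each target × ADE pair over the shared drug universe (drugs present
in both data sources; support filtering is applied after restriction to
that universe), the 2×2 table is TP/FP/FN/TN as defined in the README.
Decisions baked in:

* **EF** is precision over prevalence. For TP = 0 it is defined as 0; it
  is undefined (error) when the selected margin TP+FP is empty.
* **Fisher test is one-sided** in the enrichment direction (upper
  hypergeometric tail with margins fixed): only overrepresentation is
  hypothesized, and a two-sided test would spend power on depletion.
* **q-values** form one family per scan (all pairs jointly), consistent
  with reporting a single q per scanned hypothesis. Default method is
  Benjamini–Hochberg step-up. A Storey variant multiplies BH values by
  π̂₀ = min(1, #{p > 0.5}/(0.5·m)) at a fixed λ = 0.5 — deliberately no
  spline smoother, to keep the estimate reproducible and dependency-free.
* Selection thresholds are **strict** (EF > 5, q < 0.05) with tp ≥ 3
  inclusive; "greater than" wording is taken literally.

The scan is fully vectorized: TP counts for every pair come from one
indicator-matrix product, so the 347 × 1773 = 615,231-pair scan runs in
about two seconds on one CPU.

### Linkage and leveraging

Thresholded drug–target candidates (score ≥ 0.75, inclusive) are joined
to selected target–ADE signals on the target, giving drug–target–ADE
triples; each drug–target anchor accumulates a predicted ADE set.
Leveraging then scores each anchor's predicted set against the drug–ADE
reference: TP = predicted ∩ reference(drug), FP = predicted only, FN =
reference only, TN = the remainder of the ADE universe, followed by EF,
one-sided Fisher p, and q over all anchors jointly. The mirrored
computation re-scores drug–ADE anchors (from an external drug–ADE
predictor, thresholded at 0.75) against the drug–target reference.

Open design points resolved here:

* **TN universe**: the post-filter entity set of the corresponding scan
  (the reference's surviving ADEs or targets). The universe is not
  stated by construction anywhere, and the post-filter set is the only
  one all counted sets are guaranteed to live in.
* **Anchors with an empty predicted set are dropped**, not scored EF = 0:
  no hypothesis is made for them.
* **Ranking key** for leveraged candidates: EF descending, then q
  ascending, then lexicographic anchor ids — a deterministic choice;
  final selection is EF > 1 and q < 0.05, both strict.
* Leveraging is idempotent under duplicate triples (the predicted set is
  a set).
* A drug absent from the reference is treated as having an empty known
  set, with a warning — dropping it would silently bias precision
  upward.

### Evaluation

Positives are the known edges, negatives all other combinations — no
negative sampling, so reported precision/EF are against the full unknown
background. AUROC is computed as the normalized Mann–Whitney statistic
(ties count one half), which is the exact area under the step ROC without
binning choices. EF@k = precision@k over global prevalence; EF at full
depth is identically 1.

Hold-out splits move a uniform random fraction of known edges to the test
set (seeded); leave-class-out removes every edge of the drugs in one
class, testing recovery with no close neighbors in training. During
evaluation the training edges are removed from the ranked list entirely —
they are neither TP nor FP at test time. Per-target AUROCs are computed
within each target's own drug ranking; targets lacking a positive or a
negative are NA.

## Synthetic data: what it emulates and what it does not

`generate` draws: drug–target edges i.i.d. Bernoulli(p); drug–ADE edges
as the union of causal edges (each binder of a causally linked target
shows the ADE with probability π) and background Bernoulli noise;
similarity Beta(high) for target-sharing pairs and Beta(low) otherwise,
symmetrized with unit diagonal. Planted causal links are placed only on
targets with at least 6 binders so they survive the support filter.
ATC-like classes come from the connected components of the target-sharing
graph, chunked to a maximum class size, so leave-class-out removes real
neighborhoods. `null_permute` permutes the drug labels of the drug–ADE
table, destroying target–ADE coupling while preserving the degree
multiset.

Reference conditions:

* **Strong signal** (default): 500 drugs × 100 targets × 150 ADEs,
  p_edge = 0.02, 60 causal links, π = 0.8, background 0.02,
  Beta(4,1)/Beta(1,4) similarity (means 0.8/0.2). p_edge = 0.02 keeps
  target sharing sparse enough to be informative (expected 10 binders per
  target, about 2 targets per drug) while clearing the ≥ 5-drug filter.
* **Null calibration**: 500 drugs × 100 targets × 100 ADEs (exactly
  10,000 scanned pairs), dense margins (edge and background rates 0.1,
  expected degrees ≈ 50) and no causal links. Density matters because the
  one-sided Fisher p on a 2×2 is discrete: with degrees around 10 the
  test is visibly conservative (fraction of p < 0.05 near 0.02), while at
  degrees near 50 the achievable p-values are dense enough that the null
  fraction sits near 0.035. This is a property of the exact test, not a
  miscalibration of the scan.
* **Small fixture**: 50 × 20 × 30 for fast tests; its higher edge density
  (needed to clear the support filter at n = 50) makes target-sharing
  nearly universal, so its drug–target AUROC (~0.75–0.8) is intentionally
  weaker than the reference condition's (> 0.95). Quantitative claims are
  therefore asserted on the reference condition.

What the generator does **not** emulate: real chemistry (no molecules),
the heavy-tailed degree distributions of curated databases, correlated
assay noise, ADE ontology structure (terms are opaque strings), or
dependence between similarity and potency. Passing tests demonstrate that
the machinery recovers the structure it assumes — they are evidence of
correctness, not of real-data performance, which is bounded by the
quality of the similarity matrix and reference standards supplied.

## Numerical choices

* Fisher p via the vectorized hypergeometric survival function; verified
  against an exact integer combinatorial sum to < 1e-12 over all 635,375
  tables with N ≤ 60.
* BH q-values via the standard step-up adjustment (statsmodels), checked
  against a direct implementation of the definition.
* Similarity matrices are validated (symmetry, range, diagonal) to 1e-9
  and then snapped exactly; candidate tables are written with 6
  significant digits so repeated runs are byte-identical.
* Ties everywhere are broken lexicographically; all randomness flows
  through explicit integer seeds via numpy `default_rng`.
* Problem sizes in tests and the acceptance script: the published-scale
  identities run at full size (1526 × 726 scoring; 615,231-pair scan);
  stochastic properties use the 500 × 100 × 150 reference condition over
  5 seeds, which is large enough that the measured quantities (AUROC,
  sensitivity, precision@k) are stable to well within the asserted
  margins.

## Known limitations

* The similarity computation for 3D structures is external by design;
  only the normalization of precomputed overlap volumes is provided.
* The q-value "storey" method is the fixed-λ estimator; results can
  differ slightly from spline-smoothed π₀ estimators.
* Single-pass support filtering means entity degrees are guaranteed only
  with respect to the input table, not after subsequent universe
  restrictions.
* `score_all` materializes the full cross-product; at 10⁴ drugs ×
  10³ targets memory, not time, becomes the binding constraint.
* The leveraged q-family is one per run; merging runs requires
  recomputing q-values over the union.
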