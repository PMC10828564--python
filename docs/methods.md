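# Methods

## Problem and approach

Given a collection of DNA sequences, the task is to learn an embedding
f : sequence → R^d such that cosine similarity in R^d reproduces, as closely
as possible, the ranking induced by optimal global alignment scores. The
pipeline has four stages: (1) encode every sequence as a chaos game
representation (CGR) image, (2) compute the alignment ground truth, (3) fit
an embedder, (4) score the embedder's rankings.

## CGR encoding

The chaos game places a marker at the center (0.5, 0.5) of the unit square
and, for each base, moves it halfway toward that base's corner. Corner
assignment is A=(0,0), C=(0,1), G=(1,1), T=(1,0); nothing downstream depends
on which assignment is chosen, but everything depends on it being fixed, so
it is a documented, configurable constant. Rasterization bins the visited
points into an R×R count grid with half-open cells [i/R, (i+1)/R); chaos
game points are odd dyadic rationals and never land on a cell boundary. At
resolution 2^k the cell of a point is determined exactly by the last k bases
consumed, so the count grid (skipping the k−1 warm-up points) equals the
k-mer frequency matrix; the test suite verifies this correspondence
exhaustively for k ≤ 4. Images fed to embedders are max-normalized to [0,1].
Default resolution is 64×64; the desk-scale benchmark uses 16×16 (the k=4
equivalent), which keeps training fast while leaving the baselines a dense,
informative image.

Characters outside {A,C,G,T} cannot be placed in a 4-corner chaos game. The
reader either strips them (default, with a warning) or drops the record;
both policies are explicit because ambiguity handling changes sequence
content.

## Alignment ground truth

Similarity is the optimal global alignment score with +1 match, 0 mismatch,
−1 per gap position (linear gap model — opening and extension cost the
same). Scores are computed once per unordered pair with Biopython's
`PairwiseAligner` (global mode); an exhaustive-enumeration oracle pins the
implementation on short strings in the tests. Raw integer scores are used
for ranking without length normalization; a normalized variant
(score / max length) is easy to add but is not the default because ranking
behavior is defined on the raw scores. Ties in a ranking are broken by
ascending sequence id — an arbitrary but deterministic rule, required for
reproducible NDCG.

Every sequence serves as an anchor exactly once; the train/test split (80/20
by default) applies to the *anchor role only*, so a test anchor is still
ranked against every other sequence.

## Losses

**Triplet.** For an anchor's ranked neighbors, every ordered pair with
strictly greater score yields a triplet; tied scores yield none. The loss is
the positive part of (squared distance to positive) − (squared distance to
negative) + α, summed over the batch. Full triplet enumeration is cubic in
practice, so a per-anchor cap (default 64, seeded uniform subsample) is
applied.

**Ladder.** Each anchor's neighbor list is sliced into M contiguous
near-equal tiers (remainder to the earliest tiers; a run of tied scores
never straddles a boundary — the boundary moves forward). Tier i ≥ 2
penalizes [α_i − s̃(q,x⁺) + s̃(q,x⁻)]₊ over positives x⁺ in tier i−1 and
negatives x⁻ in tiers i..M. Tier 1 has no earlier tier; the anchor itself is
the only positive, and since the anchor's cosine to itself is identically 1
the tier-1 term is [α₁ − 1 + s̃(q,x⁻)]₊ over all neighbors. This makes tier
1 a strict special case of the general tier formula, which is how the
slightly inconsistent conventional statement of the loss (a positive term
appearing in a tier that has no positives) is resolved here.

Inside the loss, s̃ is the **embedding cosine**, not the alignment score:
the loss must be differentiable in the network weights, and alignment scores
enter only through tier construction. Defaults: M = 4, α_i = 0.1·i
(non-decreasing so deeper boundaries demand wider separation), β_i = 1.

Gradients of both losses, including the cosine chain rule, are derived by
hand and verified against central finite differences in the tests.

## Networks and training

Both architectures are built on a small numpy layer stack (valid-mode
convolution via im2col, overlapping max-pool, dense, ReLU/tanh, inverted
dropout) with an Adam optimizer; gradient correctness is pinned by
finite-difference tests rather than an autodiff framework.

* CNN: conv (kernel 5, ReLU) → 2×2 max-pool with stride 1 → dense 512 ReLU,
  dropout 0.2 → dense d, tanh. Output entries lie in [−1,1].
* FCN: flatten → dense 512 ReLU, dropout 0.2 → dense d, ReLU.

The recorded reference configuration (`PAPER_PRESET`) uses 1024 conv filters
and learning rate 6e-7, values appropriate to a large corpus and long
training schedules. **The desk-scale default deviates loudly:** 8–32
filters and Adam at 1e-3, because at 96 sequences × ≤10 epochs a 6e-7 step
size leaves the network at its initialization. The deviation is a
scaling decision, not a claim about the reference values.

Training iterates anchors in seeded random order; each step embeds the
anchor plus a seeded per-tier (ladder) or per-triplet-set (triplet) sample
of candidates, computes the loss gradient with respect to the embeddings,
backpropagates, and takes one Adam step. Per-anchor losses are normalized by
their number of hinge terms so anchors with different candidate counts
contribute comparably. A 10% slice of training anchors is held out for a
validation loss; early stopping restores the best-validation weights after
`patience` non-improving epochs. One integer seed governs initialization,
dropout, sampling and the validation split.

Degenerate embeddings: the FCN's ReLU output can in principle produce a zero
vector, for which cosine is undefined; norms are floored at 1e-12 inside the
losses and ranking (the strict `cosine_similarity` function raises instead).

## Evaluation

NDCG uses relevance = reversed true rank (n − i + 1) evaluated at predicted
positions, discount 1/log₂(i+1) (the base is configurable; base 2 is the
information-retrieval convention), normalized by the true-order DCG. The
positional rank score at position p is the mean over anchors of
exp(−|p − true rank of the item predicted at p|); positions are 1-based.
Note NDCG with this relevance profile has a high chance floor: uniformly
shuffled rankings score ≈ 0.84 on the benchmark data, so differences of a
few points are meaningful. Embedding time is reported as wall-clock per
sequence and is hardware-dependent; it is never asserted against.

## Synthetic data generator

Real collections of resistance-gene plasmids (hundreds to thousands of
sequences, lengths mostly ~800–1200 nt, grouped by pathogen) motivate the
data shape, but tests must run without downloads, so the generator creates
known ranking structure: each family descends from a random uniform-
composition ancestor, and member r carries iid per-site substitutions at
rate tier_r (default tiers linear from 0 to 0.25), optionally indels. Lower
tiers therefore have stochastically higher alignment scores to the family
ancestor, giving every anchor a graded, near-deterministic ladder.

Defaults — 8 families × 12 members, 300 nt, substitution-only — are the
desk-scale study conditions used by the benchmark and acceptance script
(96 sequences, 4560 pairwise alignments). The generator is deliberately not
an evolutionary model: no transition/transversion bias, no rate
heterogeneity, no phylogenetic branching, no horizontal transfer. Passing
benchmarks show the pipeline orders graded substitution divergence
correctly; they do not show performance on real plasmid data, where length
variation, repeats and composition bias matter.

## Benchmark findings at desk scale

Across seeds, the ladder-loss CNN's held-out mean NDCG exceeds the
flattened-CGR baseline, which in turn exceeds the triplet-loss CNN in most
seeds (the triplet model occasionally edges past the baseline); the
dimension sweep shows PCA flat-to-rising with dimension and all three hashes
degrading toward the shuffled-ranking floor at d = 16. One scaled-down
departure from the full-scale picture: the raw-image baseline wins the
*positional* rank scores here, because the lowest-mutation family member is
nearly identical to the anchor and raw image cosine identifies it trivially,
while the 64-dim CNN embedding blurs exact top-rank identity even as it
orders the full list better.

## Numerical conventions

* PCA components use a fixed sign convention (largest-magnitude loading
  positive); fitting is on training anchors' images only. In dimension
  sweeps a requested dimension above the data rank is capped to full rank —
  projection onto every principal axis already retains everything.
* Hashes emit bits as ±1 so cosine equals 1 − 2·Hamming/d. ahash thresholds
  block means at their mean (strict >, so constant images hash to all −1);
  phash takes the g×g low-frequency block of an orthonormal type-II DCT of
  the block-mean-downscaled image (4g×4g target), thresholding at the median
  of the retained coefficients excluding the DC term; whash thresholds the
  Haar approximation band at scale g at its median. Downscaling is always
  area-mean block pooling, never interpolation.
* The train/test split size is round(n × fraction), clamped so neither side
  is empty.
* All randomness flows from integer seeds through `numpy.random.default_rng`;
  no global state.

## Limitations

* The numpy networks are CPU-bound and desk-scale; they are not a training
  stack for millions of sequences.
* Full pairwise alignment ground truth is O(n²L²); the benchmark sizes keep
  this at seconds, real corpora need precomputed or cached score tables
  (`save_scores_tsv`/`load_scores_tsv`).
* Retrieval uses an exact brute-force cosine index; approximate
  nearest-neighbor structures are out of scope.
* Hyperparameters (margins, β weights, tier count M, embedding dimension)
  are exposed but not auto-tuned.
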