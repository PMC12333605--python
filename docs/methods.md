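# Methods

## Problem and model

The package scores every drug–microbe pair for plausibility of an
interaction, given (a) a binary adjacency matrix *A* (nd × nm) of known
associations, (b) drug side-effect term sets, (c) a drug chemical-structure
similarity matrix, and (d) a microbe sequence-identity similarity matrix.
The structure and sequence similarities are treated strictly as inputs:
computing them (graph matching over chemical structures, multiple sequence
alignment) is upstream of this package.

The modelling assumption is *guilt by association through similarity*:
drugs with similar structures/side effects, and microbes with similar
sequences, tend to share interaction partners. Each pair (d_u, m_v) is
therefore described by the concatenation of microbe m_v's similarity row
(length nm) and drug d_u's similarity row (length nd) — the pair's
position in both similarity spaces. Labels enter only through *A*;
features never see it, which the tests assert explicitly.

Deliberately excluded: Gaussian-kernel similarity derived from *A* itself.
Interaction-profile kernels leak label information into the features and
would inflate cross-validation estimates; the integrated similarities here
use only the raw side-effect/structure/sequence views (microbe similarity
entirely unprocessed, drug similarity the plain average of its two views).

### Missing-data conventions

* Similarity diagonals are forced to 1 on load (self-similarity).
* Drugs absent from the side-effect source contribute SS1 = 0 rows; the
  integrated drug similarity is still the literal two-source average
  (SS2/2 for such drugs). A `renormalize=True` mode averages over the
  non-zero sources instead; the literal average is the default because the
  feature construction expects a fixed, comparable scale across drugs.
* Entities present in the association table but missing from a similarity
  file get 0 off-diagonal / 1 diagonal rows — absence of evidence scores
  as no similarity, mirroring the "no common side effects → 0" convention.
* The structure cutoff (default 0.5) zeroes sub-threshold entries but keeps
  supra-threshold values continuous; a `binarize` flag exists because the
  alternative reading (hard thresholding to {0,1}) is also defensible. The
  continuous form is the default since downstream features are continuous
  similarities.

## Encoder

A small 1-D CNN compresses each (nm+nd)-vector to ⌊(nm+nd)/2⌋ latent
features: conv (16 filters, width 16, stride 1, valid padding, ReLU) →
max-pool (width 2) → dropout → dense ⌊(nm+nd)/2⌋ (ReLU) → dropout → dense 1
(sigmoid). The head is trained with Adam on binary cross-entropy over the
balanced pair sample; encoding uses the penultimate activations with
dropout off, so it is a deterministic row-wise map. At the published
dataset scales this gives 773 latent features for 1,373 + 173 entities and
930 for 1,720 + 140 (the floor only matters for odd nd + nm).

The implementation is plain numpy with explicit forward/backward passes —
at these sizes (tens of thousands of parameters, hundreds to thousands of
training rows) that is fast, dependency-free, and exactly reproducible
from a seed; the backward pass is verified against finite differences in
the tests.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| filters / kernel / pool | 16 / 16 / 2 | fixed architecture of the method |
| dropout rate | 0.5 (both sites) | standard regularisation for small dense nets |
| epochs | 20 | the sweet spot of the epochs sweep {10, 20, 50, 100} |
| batch size / learning rate | 32 / 1e-3 | conventional Adam settings |
| padding / stride | valid / 1 | compression intent; no length-preserving padding |

Stride, padding, dropout rate, batch size and learning rate are design
choices of this package (the architecture lineage fixes only filter
counts/sizes); all are exposed on `EncoderConfig`.

## Bernoulli random forest

The forest departs from CART-style random forests in three coupled ways:

1. each tree's (optionally bootstrapped) sample is partitioned into a
   structural half that alone determines splits and stopping, and an
   estimation half that alone fills leaf positive-fractions;
2. trial B1: with probability p1 a node draws one candidate feature,
   otherwise ⌈√D⌉ distinct ones;
3. trial B2: with probability p2 the split threshold is uniform on the
   chosen feature's value range, otherwise the Gini-optimal midpoint over
   candidates × consecutive distinct values.

This keeps the estimation step independent of the structure search (the
ingredient behind consistency arguments for such forests) while the small
Bernoulli probabilities keep accuracy close to a deterministic Gini
forest.

Numerical conventions: samples route left iff x ≤ threshold; Gini ties
break to the lowest feature index, then the smallest threshold (tolerance
1e-12); structural/estimation split size is round-half-up; a random
threshold that separates nothing structurally makes the node a leaf.
Leaves reached by no estimation sample inherit the nearest ancestor's
fraction (root fallback: the global estimation fraction).

Defaults and why: p1 = p2 = 0.05 (the mechanism stays active but trees are
near-deterministic; no canonical values exist for this method), 100 trees,
min_split 10 structural samples, max_depth 25, bootstrap on,
structural_fraction 0.5. `share_data=True` collapses the partition so the
degenerate limit (p1 = p2 = 0, no bootstrap) can be checked tree-by-tree
against an independent brute-force CART implementation — the tests do
exactly that on ≤50-sample instances.

## Negative sampling

Positives are all A = 1 pairs; negatives are drawn 1:1 from the unlabeled
pool. This treats unlabeled pairs as negative — defensible because true
associations are a tiny fraction of the nd × nm grid, but it is a known
bias (some "negatives" are undiscovered positives). Two samplers:

* **random** — uniform without replacement;
* **DAS** — densities = number of neighbours within a radius (Euclidean on
  raw pair features), pool sorted by density descending (ties by pool
  index), then systematic selection at indices ⌊k·|pool|/n⌋ so every
  density stratum is represented.

DAS choices made here (the method's description leaves them open): raw
rather than encoded features; auto-radius = 25th percentile of pairwise
distances in a ≤1000-point seeded subsample; pools above 20,000 points get
densities estimated against a seeded subsample of that size, with the
exact mode available. All configurable.

During cross-validation the unlabeled pool still contains the held-out
positives (from the training view they are unlabeled); the resulting
mislabeling risk is accepted because of the low positive rate.

## Evaluation protocol

5-fold cross-validation over the known associations, repeated (default 10
times; each repeat reshuffles the folds). Per fold: zero the held-out
positives in the training view, rebuild the balanced training set, retrain
encoder + forest, score all pairs, and compare held-out-positive scores
against the scores of every pair unlabeled in the *full* dataset. The fold
AUC is the tie-aware Mann–Whitney statistic — with heavily tied forest
scores at small tree counts, ½-credit tie handling is essential. The
reported spread is the population standard deviation over all fold AUCs;
a repeat-means mode exists behind `std_mode`. Training-sampled negatives
stay in the evaluation pool by default (they are unlabeled); an exclusion
mode exists. PR curves enumerate every distinct threshold; the correlation
diagnostic reports the distribution of absolute off-diagonal Pearson
correlations between latent features (constant columns flagged, 0 by
convention).

The case-study workflow masks one drug's associations, retrains, and ranks
that drug's candidate microbes; recovery of the masked associates in the
top-k is the success measure. Reference classifiers (scikit-learn random
forest, logistic regression, kNN, and the encoder head alone) sit behind a
config switch for comparison runs; they are thin local baselines, not
reproductions of external published models.

## Synthetic data

The generator plants `n_blocks` co-association clusters: contiguous
drug/microbe blocks, within-block similarity 0.8 vs 0.1 across (plus
symmetric uniform noise, clipped, unit diagonal), associations Bernoulli
(0.3 within-block vs 0.01 background), and side-effect profiles built from
per-block core term groups (kept with probability 0.9) plus a shared noise
pool (0.05), so Jaccard similarity tracks block membership. A block model
was chosen over a latent-factor model because "similar entities share
associations" is exactly a cluster assumption.

Defaults — 120 drugs × 40 microbes, 4 blocks, seed 7 — are the package's
study conditions: large enough that 5-fold CV has ~80 held-out positives
per repeat, small enough for fast full-pipeline runs. What passing on this
data shows: the pipeline recovers planted block structure well above
chance (CV AUC > 0.85) and sits at chance when labels are shuffled. What
it does not show: performance on real pharmacological data, whose degree
distributions are heavy-tailed, whose similarity matrices are not
block-structured, and whose label noise is not uniform — none of which
the generator mimics.

A fixed 4-drug × 3-microbe miniature with hand-written matrices
(`generate_worked_micro`) documents every intermediate (Jaccard values,
cutoff effects, pair vectors) for step-by-step assertions.

## Problem sizes and determinism

Cross-validation tests and the acceptance script use single-run 5-fold CV
on the default synthetic conditions, and reduced configurations (2–3
epochs, 5–20 trees, nd ≤ 40) for protocol-level tests — the package's own
choice of desk-scale problem sizes. One master seed fans out to stage
seeds via stable hashing (negatives / encoder / classifier / folds), so a
fixed seed makes folds, samplers, initialisation, forest growth and score
files byte-identical across runs; all randomness flows through
`numpy.random.Generator`.

## Known limitations

* The unlabeled-as-negative assumption biases both training and the
  evaluation pool.
* Cold-start drugs/microbes (all-zero similarity rows) get uninformative
  features; the masked-drug protocol only masks associations, not
  similarity information.
* The encoder is intentionally small; no hyperparameter search is
  performed beyond the epochs sweep exposed on the CLI.
* Exact DAS densities are quadratic in pool size; above the 20,000-point
  cap they are subsample estimates.
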