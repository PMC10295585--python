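# Methods

## Problem and model

`ncrna_funclass` predicts the functional class of a non-coding RNA (tRNA,
miRNA, snoRNA subclasses, ribozymes, …) from its primary sequence alone —
no secondary-structure prediction. The classifier is a hybrid of local and
global sequence information:

* **Local branch.** The sequence is one-hot encoded over the channels
  (A, C, T, G) — U is folded into T, any other symbol becomes the zero
  row — into a fixed `max_len × 4` matrix (right zero-padding, truncation
  beyond `max_len`). A strided convolution whose kernel spans all four base
  channels (kernel 5 along the sequence, stride 2, 128 filters), followed
  by a cascade of 1-D convolutions with the same kernel/stride/filter
  settings, each conv followed by average pooling (window 2) and ReLU,
  produces a flattened local representation.

* **Global branch.** Up to three whole-sequence summary vectors are fed to
  a small dense stack (ReLU, dropout):

  - **KM** — the normalized overlapping k-mer spectrum, `4^k` components
    summing to 1 (default `k = 6`, 4096 features). The chance that a given
    k-mer appears in a random sequence of length `n` is
    `1 − (1 − 4^{−k})^{n−k+1}`, which motivates keeping k small: short
    words occur often enough to carry stable compositional signal.
  - **SP** — sequence-pattern class propensities. For every length-`L`
    pattern `p` (default `L = 11`) seen in ≥ `min_support` training
    sequences, the table stores `P(class = c | p in s) = N(c,p) / N(p)`,
    where `N(c,p)` counts *sequences* of class `c` containing `p` (presence
    at sequence level). A query is encoded as the occurrence-weighted mean
    of the propensity rows of all patterns it contains; each matching
    window position contributes its pattern's row once, which realizes
    `Σ_p count_occurr(p,s)·P(c|p) / Σ_p count_occurr(p,s)`. If nothing
    matches, the encoder returns the uniform vector `1/|C|` — the only
    choice that keeps the sum-to-1 invariant while adding no information.
  - **IB** — instance-based propensities. The query is compared to the
    training instances by exact Needleman–Wunsch global alignment with an
    identity substitution matrix (match 1, mismatch 0) and linear gap
    penalty −1. A fast seed stage ranks references by the number of shared
    `seed_k`-mers (default `seed_k = 11`) and only the best
    `candidate_pool` (default 50) are aligned; the prefilter can be
    disabled, in which case the result provably equals the exhaustive
    all-pairs computation (tested). The `top_n` (default 5) best hits vote
    for their classes with weight `max(score, 0)`; if all scores are
    non-positive the vector is uniform.

* **Output head.** The flattened local representation and the global-branch
  output are concatenated immediately before a dense softmax layer with one
  neuron per class. Categorical cross-entropy `−Σ_i t_i log p_i` is
  minimized with Adam (learning rate 0.5 × 10⁻³, batch size 32).
  Output-level concatenation is the default; an alternative injection mode
  stacks each global vector — linearly resampled onto the `max_len` grid —
  as an extra input channel of the convolutional branch. The output mode
  trains better in practice (the two information types are merged as late
  as possible) and the input mode is retained only for ablation.

The output activation is softmax: classes are mutually exclusive and the
loss is categorical cross-entropy, which requires a distribution over
classes rather than independent sigmoids.

## Training protocol

`fit` splits the labeled data 80/20 (stratified by class, seed-determined)
into a backpropagation set and a validation set. All global-information
state — the SP table and the IB reference instances — is built from the
80% part only; validation and test sequences never contribute to it.
IB features *for the training sequences themselves* are computed
leave-one-out (each sequence's self-hit is excluded): including the exact
self-match would hand the network its own label during training. Training
runs for `max_epochs`; the weight snapshot of the epoch with the highest
validation accuracy (ties → earliest) is kept.

The split is stratified even though a plain random split would also be
defensible; stratification guarantees no class vanishes from the small
validation set at desk-scale sample sizes.

## step75

`step75` measures training speed: the first (1-based) optimizer step at
which training-batch accuracy reaches 75%. Raw batch-of-32 accuracy has a
granularity of 1/32 and is noisy, so the crossing is computed on an
exponentially smoothed series (`s_1 = a_1`,
`s_t = 0.1·a_t + 0.9·s_{t−1}`). If the threshold is never reached the
value is reported as "not reached"; in aggregated ablation tables such
runs enter the mean as (total steps + 1), a conservative penalty.

## The neural-network core

No deep-learning framework is a dependency: the layer set the architecture
needs (strided 1-D convolution via im2col, average pooling, dense, ReLU,
inverted dropout), explicit backpropagation and an Adam optimizer are
implemented directly in NumPy (`_nn.py`). The backward passes are verified
against central finite differences in the test suite, and training is
bit-reproducible for a fixed seed in single-threaded runs: initialization
(Glorot uniform), batch shuffling and dropout masks all draw from
generators spawned from one seed.

Alignment scoring is delegated to Biopython's `PairwiseAligner` (global
mode) and is checked against a brute-force alignment-path enumeration
oracle on short strings. Confusion matrices come from scikit-learn;
precision/recall/F1 are computed from the matrix one-vs-rest, with
precision defined as 0 for a class never predicted. Reported F1 is the
macro (unweighted) mean over classes — the common choice for imbalanced
multi-class RNA benchmarks; accuracy is trace/total of the confusion
matrix.

## Synthetic data

`simulate.generate_dataset` draws, per class: a length from a normal
distribution truncated below at `max(motif length + 1, 20)`; background
residues i.i.d. from a class-specific base composition; and, with
probability `motif_prob`, one planted motif (chosen uniformly from the
class's motif set) at a uniform position, with per-base substitution noise
at `mutation_rate`. `default_13class_specs` instantiates the 13 canonical
ncRNA classes with their published length statistics (e.g. tRNA 78 ± 13,
5S rRNA 119 ± 9, Intron gpI 342 ± 99). The printed miRNA statistic
(10 ± 41) admits non-positive lengths and is replaced by (100, 20), a
plausible pre-miRNA scale. Default study conditions are `motif_prob = 0.8`
and `mutation_rate = 0.05` — strong but imperfect class signal — with two
seeded random motifs of length 11 per class and mildly distinct
compositions (Dirichlet(25) around uniform).

This generator produces exactly the two signal types the global channels
detect — compositional bias (KM) and recurrent medium-length patterns
(SP, IB) — and nothing else: no secondary structure, no covariation, no
family-level homology gradients. Passing tests therefore demonstrate that
the machinery recovers planted structure and that the ablation ordering
holds under these conditions, not that real-data accuracies are
reproduced.

## Problem sizes and numerical choices

The ablation study in the tests and in `scripts/acceptance.py` runs at desk
scale: 13 classes × 100 training + 50 test sequences, three seeded repeats,
20 epochs, convolution width 64 and `max_len = 600` (the synthetic length
distributions put ≪ 1% of sequences beyond 600 nt). Library defaults keep
the full-size configuration (128 filters, `max_len = 800`, 100 epochs).
Other defaults: dropout 0.3, global-branch MLP sizes (64, 32), two 1-D
convolution layers — values in ranges where the architecture is
insensitive at desk scale.

Degenerate inputs are handled explicitly: empty sequences are errors; a
k-mer window longer than the sequence yields the all-zero spectrum; an
empty pattern table (nothing reaches `min_support`) warns and every query
then encodes as uniform; alignment candidate ties are broken by stable
sort order (reference order), making results independent of hash
iteration.

## Known limitations

* The IB seed-and-extend prefilter is a heuristic: a reference sharing no
  length-11 words with the query is never aligned even if its optimal
  alignment score would rank in the top hits. The exhaustive path
  (`use_prefilter=False`) is exact but quadratic.
* How a heuristic database search and exact global alignment would best be
  fused into a single IB vector is open; this implementation exposes the
  prefiltered and exhaustive paths rather than a fusion rule.
* Training determinism holds within a fixed BLAS configuration;
  multi-threaded BLAS reductions may reorder sums across machines.
* `max_len` truncation discards 3'-terminal information of very long
  sequences (rare in the intended length regime).
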