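# Methods

## Problem setting

Given a tumor cohort — a gene × sample expression matrix, a binary gene ×
sample somatic mutation matrix, a confidence-weighted PPI network, and a
list of known driver genes — the package produces a cohort-level ranking
of candidate driver genes. The method treats driver identification as link
prediction on a bipartite gene–sample graph followed by rank aggregation,
so that genes are scored per sample first and the cohort ranking reflects
agreement across heterogeneous patients rather than a single pooled
statistic.

## Preprocessing

Expression is standardized per gene across samples, z = (x − μ)/σ. σ is
the population standard deviation by default (`ddof` configurable);
constant genes get z = 0 and can never be flagged. An entry is *aberrant*
when z ≥ 2; a `two_sided` switch flags |z| ≥ 2 instead, off by default
because driver-induced perturbations are modeled as activating shifts.
Because z-scores are invariant under per-gene affine rescaling of
expression, the flags do not depend on measurement units (a property the
tests check).

A mutated gene is retained iff in some sample where it is mutated at least
one PPI neighbor is aberrant *in that same sample* (the DriverNet-style
coupling of mutations to downstream expression change; a cohort-level
coupling is available behind `same_sample=False`). Genes never mutated are
outside the prediction universe. PPI edge lists are thresholded at load
time (≥ 0.5 by default, matching CPDB-style confidence scales; a
strict-greater mode covers STRING's > 0.85 convention), self-loops are
dropped, and duplicate pairs collapse to their maximum confidence.

The retained genes (sorted lexicographically — index order is fixed before
any randomness) define three shared-index matrices: gene features Xg
(mutation profiles, G × N), sample features Xs (expression profiles,
N × G), and the association matrix A with A[i,j] = 1 iff gene i is a known
driver mutated in sample j. A ≤ Xg entrywise by construction.

## Model

**Encoder.** Two bipartite GraphSAGE layers (depth configurable to 1)
update both node types simultaneously:

    Hg ← ReLU(Hg Wg,self + Ãgs Hs Wg,neigh)
    Hs ← ReLU(Hs Ws,self + Ãsg Hg Ws,neigh)

Ãgs = D⁻¹A and Ãsg = D⁻¹Aᵀ are row-normalized adjacencies; zero-degree
rows stay zero, so isolated nodes propagate self-features only (no
self-loop injection). The aggregation adjacency is the association matrix
A by default; to prevent label leakage, columns of held-out samples are
zeroed during both training and inference, so a test sample's embedding
derives only from its own expression features. `adjacency_source =
"mutation"` switches to the label-free mutation matrix. Optional
fixed-size neighbor sampling sparsifies each direction's adjacency to at
most `sampling_size` neighbors (uniform, without replacement) before
normalization — the dense normalized form is the reference path, and the
sampled adjacency is redrawn every epoch with the epoch index folded into
the seed. Final scoring always uses the dense adjacency at the fitted
parameters.

**Cross-attention.** Single-head scaled dot-product attention runs in both
directions between the encoder outputs G and S: for the gene side,
E = softmax(G WQ (S WK)ᵀ/√dk), Ĝ = ReLU((E · S WV) Wp + bp), and
symmetrically for samples. Each direction has its own Q/K/V set by default
(`share_qkv` reuses one set); Q/K/V projections are bias-free and there
are no residual connections — the block is deliberately minimal. Attention
rows are stochastic by construction; permuting key order permutes nothing
but the corresponding output rows (both properties are tested).

**Decoder and loss.** Linear maps W0, W1 (no activation) project both
embeddings into a common k-dimensional space; the decoded probability is
Âᵢⱼ = (cos(h_gᵢ, h_sⱼ) + 1)/2 ∈ [0, 1], with zero-norm rows decoding to
0.5 (cosine defined as 0). The loss is weighted binary cross-entropy over
the masked pairs,

    L = −(1/|M|) Σ_{(i,j)∈M} [β Aᵢⱼ log Âᵢⱼ + (1 − Aᵢⱼ) log(1 − Âᵢⱼ)],

with probabilities clipped into (1e−7, 1 − 1e−7). Driver-positive pairs
are typically two orders of magnitude rarer than negatives, so β defaults
to the negative:positive ratio inside the mask; the mask itself is all
gene rows × training-fold sample columns. The loss is implemented with a
scalar β; per-pair weight matrices are not supported.

**Optimization.** The model is small and dense, so it is implemented
directly in NumPy with hand-derived reverse-mode gradients through every
block (ReLU GraphSAGE layers, softmax attention, projections, row-wise
cosine, weighted BCE) and trained with Adam (lr 1e−3, 200 epochs by
default). Gradients of the full composite are verified against central
finite differences for every parameter tensor and every architecture
variant in the test suite (relative tolerance 1e−4, with an absolute floor
of 1e−8 because vanishing gradients reduce central differences to
cancellation noise). Training is deterministic given the seed; a
non-finite loss aborts with `TrainingDiverged`.

## Ranking

Per sample, genes mutated in that sample are sorted by Âᵢⱼ descending
(ties by symbol) and the top ⌈0.5·m⌉ form the candidate list — the ceiling
convention lets a sample with a single mutated gene still vote. EPV then
contests every ordered gene pair in every sample: a listed gene beats each
gene it outranks and each unlisted gene, casting strength
w(r) = e^(−α(r−1)). The implementation aggregates prefix sums per list
(O(m + U) per sample instead of O(U²)) and is verified exactly against a
brute-force enumeration of all pairs. P = win/(win + loss), with P = 0 for
genes entering no contest; output order breaks ties by P, then win
strength, then symbol, so runs are byte-reproducible. The voting universe
defaults to the union of all candidate lists — a gene outside every list
scores 0 regardless, but restricting the universe does change
absent-opponent tallies, so an explicit wider universe (e.g. all retained
genes) can be passed. α defaults to cohort-specific calibrations when a
dataset tag (BRCA 0.9, LUAD 0.3, PRAD 0.6) is supplied and 0.5 otherwise.
"Standard Condorcet" is interpreted as Copeland-style win-proportion
ranking with unit vote strength, which coincides with EPV at α = 0 — the
two independent implementations cross-check each other.

## Evaluation protocol

Samples are split into k = 5 folds (seeded shuffle, contiguous chunks;
sizes differ by ≤ 1). Each fold trains on the other folds' columns and
builds candidate lists for its own test samples only. Per-fold EPV
rankings are scored with top-K precision/recall/F1 against the known
driver set over a configurable K grid (default 10…200), and the mean
across folds is reported alongside the per-fold values; a pooled ranking
aggregates every sample's held-out list into one cohort list. Negative
controls: `edge_shuffle` rewires the PPI with degree-preserving
double-edge swaps (rejecting self-loops and duplicates, confidences
carried along), and `node_shuffle` permutes gene labels on the intact
topology, redrawing the permutation if it is the identity. `topk_overlap`
computes Venn-region counts of top-K lists across networks. The ablation
harness runs all 8 combinations of encoder depth (1/2), attention
(on/off — off feeds encoder output straight to the decoder projections),
and ranking strategy (EPV/Condorcet).

## Synthetic cohorts

The generator emulates the causal structure the preprocessing filter
assumes. Defaults: 200 genes, 50 samples, 20 planted drivers; drivers
mutate per sample with rate 0.3, passengers 0.05; baseline expression is
per-gene Gaussian noise with unit SD; a driver mutation in a sample adds
+3 baseline SDs to each PPI neighbor's expression in that sample (shifts
from multiple mutated neighbors add). Expressing shifts in per-gene SD
units makes them directly comparable to the z ≥ 2 aberrance threshold.
The network is Erdős–Rényi with edge probability 0.02 (mean degree ≈ 4 at
200 genes) plus a minimum-degree-1 repair — an isolated "driver" could
never perturb downstream expression and would be biologically inert; a
Barabási–Albert option provides heavy-tailed degrees. At these settings a
binomial calculation (confirmed by the tests) gives planted drivers
near-certain survival of the mutation–aberration filter via their own
induced neighbor shifts, while background coincidences retain a gene only
at ~0.1–0.2 per mutated sample; label-permuting the network therefore
drops a few drivers from the candidate universe per cohort, which is the
channel the node-shuffle negative control exercises — as in real cohorts,
the PPI enters the pipeline only through the filter.

What the simulator does *not* emulate: realistic mutation spectra or
expression distributions, copy-number or methylation signal,
subtype-specific (sample-context-dependent) driver activity, and
correlated passenger structure. Two consequences matter for interpreting
results. First, passing tests show the machinery is correct and that the
pipeline recovers planted signal; they do not certify performance on real
tumor data. Second, because planted driver-ness is global rather than
sample-specific, the cross-attention block has little extra structure to
capture here and the measured gap between the full and attention-off
configurations on synthetic cohorts is small (the directional comparison
in the acceptance tests reflects this honestly).

## Numerical and design choices

- Population σ in the z-score (sample σ selectable); flags at the z = 2
  boundary can differ between the two conventions.
- Probability clipping ε = 1e−7 keeps logs finite; β must be > 0.
- Row normalization, cosine, and EPV all define 0/0 as 0 (zero rows,
  zero-norm embeddings score 0.5 by the cosine convention, genes with no
  contests score P = 0).
- Tie-breaks everywhere are deterministic: score desc → win desc → symbol
  asc for rankings; symbol asc within equal scores for candidate lists.
- Default problem sizes in the acceptance studies (hidden width 32,
  attention width 32, projection width 16, 200 epochs, 3–5 cohort draws)
  are chosen so a full study runs in seconds on one CPU while the planted
  signal is comfortably recovered.
- Checkpoints serialize every parameter tensor plus architecture metadata
  to a single `.npz`; the run manifest records the full configuration,
  seed, and package version, sufficient to reproduce every output file.

## Known limitations

- No GPU path and no minibatching: cohorts are assumed to fit in memory
  (hundreds to low thousands of genes after filtering).
- No early stopping or validation-split scheduling; training length is a
  fixed hyperparameter.
- Single-head attention only; no residual connections or layer norm.
- The mutation matrix is taken as given (no MAF parsing or variant-level
  filtering), and expression is used raw — users with heavy-tailed
  platforms should transform upstream.
- Per-pair loss weights beyond the scalar β are not implemented.
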