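# Methods

## Problem and scope

seqrefine addresses fixed-backbone protein sequence design (inverse
folding): given per-residue backbone heavy atoms (N, CA, C, O) of a single
chain, predict a per-residue distribution over the 20 amino-acid types and
design a sequence. The package implements a *refinement* strategy: an
existing base design model's per-residue probabilities are denoised by
entropy-based selection, the retained residues become visible context for a
structure-conditioned sequence-inpainting network, and the two predictions
are fused position-wise. The network itself, the training scheme, the
selection/fusion strategy and a synthetic data generator are all
first-class, tested components; base models (GVP-GNN, ProteinMPNN, ESM-IF1)
are treated strictly as input files (an N x 20 probability TSV).

## Graph representation

A directed k-nearest-neighbor graph (default k = 30, CA distance) is built
over residues. Distances are quantized to 1e-6 A before sorting so that
exact geometric ties — which genuinely occur on ideal-geometry backbones —
and floating-point jitter from rigid transforms resolve identically
(lower-index neighbor first). Every node has exactly min(k, N-1) neighbors,
so no padding is required.

Node features: sin/cos of the backbone torsions phi, psi, omega (angles
undefined at a terminus encode as (0, 0)), plus unit vectors to CA_i from
the next and previous CA. Edge features for v_j -> v_i: Gaussian
radial-basis encodings (16 bases, centers evenly spaced on [2, 22] A, width
= spacing) of all 25 ordered atom-pair distances among {N, CA, C, O,
virtual CB} of j and i; a one-hot encoding of the sequence offset i - j
clipped to [-32, 32]; and the unit CA_j -> CA_i direction. The virtual
C-beta uses the fixed ideal-tetrahedron construction
CB = CA - 0.58273431 (b x c) + 0.56802827 b - 0.54067466 c with b = CA - N,
c = C - CA, which is defined for glycine and exactly rigid-motion
equivariant.

Raw features pass through two geometric-vector-perceptron (GVP) layers per
feature set: scalar channels mix with the norms of linearly combined vector
channels (16 vector channels by default), so scalar outputs are exactly
rotation- and translation-invariant while chirality still enters through
the torsion signs (a mirrored backbone gives different features). The edge
GVP's vector set couples the inter-residue direction with the chain
directions of the receiving node, since the norm of a single unit vector
carries no orientation information. The 21-symbol residue token (20 amino
acids + unknown) is embedded by a learned table (width 16) and concatenated
with the structural node embedding before a linear map to width d. H0 is
therefore invariant under rigid motion and depends on position i's token
only at row i.

## Memory-efficient global graph attention

Each of L layers computes single-head attention over *all* residue pairs:

    A = softmax_row(Q K^T / sqrt(d) + B),
    B_ij = w_B . e_ij   if j is a graph neighbor of i,
    B_ij = w_B . beta   otherwise (including j = i),

where beta is the layer's learnable pseudo edge feature shared by all
non-existing edges. Node update: attention-weighted sum of values
concatenated with the gamma-normalized sum of neighbor edge features
(gamma_i = sum of A_ij over neighbors), mapped by W_N, residual, layer
norm. Edge update: [h_i || e_ij || h_j] W_E, residual, layer norm, for
graph edges only. The output head is a per-residue softmax over 20 types;
decoding is one-shot (no autoregression).

On the inference path the score matrix is streamed in 64-row query chunks
and the pseudo bias enters as one scalar, so additional memory is
O(N k + L); the measured log-log slope of peak memory vs N is ~1 for this
variant and ~2 for the dense reference variant that stores (N, N, d) edge
features. The training path materializes the (N, N) score matrix (not the
(N, N, d) edge tensor), acceptable at training problem sizes; a test pins
the two paths to each other at 1e-10.

Reference variants: `attention_layer_dense` implements the conventional
formulation on fully connected edge features and serves as the exact
oracle (the sparse layer with a complete graph reproduces it to < 1e-6
when the dense diagonal slots carry the pseudo edge feature — the caller
owns that choice, since a k-NN graph defines no self-edges; the dense
*featurization* path instead uses true self-pair features: zero distances,
zero direction). `attention_layer_local` restricts the softmax to graph
neighbors (ablation).

Numerical choices: layer norm is per-node/per-edge over the d features
(eps 1e-5); gamma is clamped at 1e-12 so an isolated node (N = 1)
contributes a zero edge aggregate instead of 0/0; softmax subtracts the
row max; vector norms inside GVPs use sqrt(sum + 1e-8). All computation is
float64.

## Training scheme

Corruption: exactly round(0.70 N) positions are masked to the unknown
token (uniform without replacement) and round(0.03 N) of the *visible*
positions are replaced by an amino acid drawn uniformly from the 19
non-native types; replaced positions stay visible. The 3% is read as 3% of
total length (equivalently 10% of the visible 30%); drawing among visible
positions is what makes the corruption an input-noise model rather than
extra masking. Loss is mean negative log-likelihood over all positions by
default (`masked_only` is available), log clamped at 1e-12.

The trainer precomputes sequence-independent featurization per structure,
draws a fresh corruption per example per epoch, accumulates gradients over
mini-batches of 8 and steps Adam (lr 1e-3 unless stated). Gradients come
from a small reverse-mode tape written for this package and are verified
against central finite differences (worst relative error ~1e-4 across all
parameter groups). Validation uses one frozen corruption per held-out
structure; the best-validation-loss checkpoint is returned. Identical
seeds give bitwise-identical loss curves.

Architecture defaults are d = 128, L = 3, k = 30 with scaled-uniform
(Glorot) initialization from a recorded seed. The printed experiments use
d = 64 (main toy benchmark) and d = 32, L = 2 (paired ablation), chosen as
single-CPU desk-scale sizes; the contracts they check are
size-independent.

## Entropy-based selection and fusion

For a base profile p^b, per-row Shannon entropy en^b (nats, 0 ln 0 = 0) is
computed; the floor(keep_fraction N) lowest-entropy positions are retained
as visible context with token = base argmax (entropy ties break to the
lower index, argmax ties to the earlier letter in alphabetical order), and
everything else is masked. The refiner's output p with entropy en is fused
per position:

    p_hat = exp(-en) / (exp(-en) + exp(-en^b)) * p
          + exp(-en^b) / (exp(-en) + exp(-en^b)) * p^b,

a convex combination dominated by the more confident source; the design is
argmax(p_hat). Validated keep fractions per base model: GVP-GNN 0.10,
ProteinMPNN 0.10, ProteinMPNN-C 0.15, ESM-IF1 0.35; unknown base models
default to 0.15. In partial design, given residues are authoritative and
copied verbatim to the output; no fusion is applied.

Mutation scanning masks one candidate site at a time, records the
predicted probability of the target type from the full remaining context,
and combines it with the CA distance to a user-supplied binding center.
How the two are combined is not fixed by any external convention; this
package uses percentile ranks,
score = w rank(prob, desc) + (1 - w) rank(dist, asc) with w = 0.5 by
default, so the two scales never need calibrating against each other.
Surface-site lists and binding centers are inputs, not computations.

## Synthetic data generator

`generate_backbone` builds chains from internal coordinates (N-CA 1.458 A,
CA-C 1.525 A, C-N 1.329 A, ideal angles, omega = 180 deg) with
motif-driven torsions: helix (-57, -47), strand (-120, +120), coil drawn
from a broad torsion box (phi in [-160, -50], psi in [-70, 160] deg). The
carbonyl O is placed in the C_i plane opposite the bisector towards
N_{i+1}. Ground-truth torsions are stored on the structure and round-trip
through the featurizer to 1e-4 rad at zero noise.

`couple_sequence` maps local descriptors — 60-degree phi/psi bins (offset
by half a bin so motif torsions sit mid-bin, never on a boundary),
CA-contact count within 8 A bucketed by 4, terminal flag — through a
seeded random lookup table to an amino acid. The map is a deterministic
function of geometry, so at zero coordinate noise the Bayes-optimal
recovery from structure is 100% (a nearest-neighbor classifier on the
binned descriptors attains it).

`make_toy_dataset` couples the sequence to the *clean* geometry and adds
coordinate noise afterwards; noisy datasets therefore emulate near-native
conformations whose observed geometry underdetermines the native sequence,
the regime where sequence context carries information beyond structure.

`simulate_base_profile` emulates a base model with controllable overall
accuracy, confidence-correctness coupling and sharpness: each position's
argmax is native with probability `accuracy`; with probability `coupling`
the row's mixing weight towards its argmax is drawn high for correct and
low for incorrect positions (U(0.65, 0.95) vs U(0.05, 0.45)), otherwise
independently (U(0.05, 0.95)); `concentration` exponentiates the weight
(one-hot rows in the limit). With accuracy 0.5 and coupling 0.95 the
lowest-entropy decile is far more accurate than the base overall, which is
precisely the structure the selection strategy exploits.

What the toys do not model: side chains, packing constraints, long-range
sequence correlations beyond the descriptor classes, real Ramachandran
densities, chain breaks. Passing the toy benchmarks shows the pipeline
learns and exploits a recoverable structure-to-sequence signal and that
the refinement machinery behaves as specified — not that the tiny trained
model transfers to real proteins.

## Evaluation protocols

Recovery is the fraction of identical positions; nssr counts pairs with
BLOSUM62 score strictly > 0 (table vendored in canonical alphabet order
and cross-checked against Biopython); perplexity is exp(mean NLL), base e.
Median confidence intervals use the percentile bootstrap of the median
(10,000 resamples, seeded).

The paired ablation (default corruption vs all-masked training) is scored
by full-sequence recovery of the one-shot output given a 30%-visible
native partial input — the entire-design scoring convention, under which
the ability to propagate visible context is rewarded. Hidden-position-only
scoring would not separate the models on zero-noise toys, where structure
alone already determines every residue.

## Known limitations

- Single chains only; no mmCIF, no multi-model ensembles, no ligands.
- The edge update is the simple concatenation form; it does not enforce
  triangle-inequality consistency between updated edges.
- Single-head attention, as in the defining equations; multi-head is a
  possible config extension, not implemented.
- The trainer is a desk-scale reference (CPU, float64, no data
  augmentation); it is not intended to reproduce benchmark-scale models.
- tracemalloc-based memory measurement tracks numpy allocations only; it
  is a relative scaling probe, not an absolute footprint.
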