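# Methods

`gofuse` predicts Gene Ontology (GO) term probabilities for a single protein
chain from two modalities — a per-residue sequence embedding matrix
M ∈ ℝ^{L×1280} and the residue contact graph of the chain's 3-D structure —
and explains its predictions at residue resolution through its
cross-attention weights. This note records the model, the conventions and
numerical choices behind the implementation, what the synthetic data
generator does and does not emulate, and the package's known limitations.

## Model

**Sequence branch.** Three parallel gated convolutional layers (GLU-style:
`conv_a(M) ⊙ σ(conv_b(M))`, 'same' zero padding, no stride or dilation) with
kernel sizes 3, 5 and 7 each map M from 1280 to 512 channels. Their
concatenation (L×1536) passes through a per-residue fully connected layer to
the intermediate representation D ∈ ℝ^{L×512}. Each of D's 512 channels is
then treated as a length-L signal and transformed with an orthonormal DCT-II;
the per-channel spectrum is summarized to one scalar, the 512 summaries pass
through a bottleneck MLP (512 → 128 → 512, ReLU) and a sigmoid, and the
resulting channel weights w ∈ (0,1)^{512} rescale D:
X = D ⊙ w (squeeze-excitation-style frequency-domain channel attention).

Two choices here are genuinely open and are resolved as follows:

* *Spectrum summary.* With one channel per part (dim′ = 1) each channel's
  spectrum has length L, but the excitation MLP needs a fixed-width input.
  The default summary is the mean absolute DCT coefficient (total spectral
  magnitude, length-invariant). The DC coefficient alone (`"dc"`) and a
  low-frequency band mean (`"lowk"`, first 8 coefficients) are config
  options. Note one degeneracy: reversing a channel flips the sign of every
  odd coefficient, so |DCT|-based summaries cannot distinguish a signal from
  its reversal; generic permutations are distinguished.
* *Output form.* Read literally, the attention equation makes the sigmoid
  output itself the sequence representation, while the surrounding design
  treats it as a weight. The default applies it as a channel reweighting of
  D (the convention of the frequency-channel-attention literature); the
  literal broadcast form is available as `freq_variant="literal"`.
* `freq_enabled=False` sets w ≡ 1 (the ablation switch).

**Structure branch.** The contact graph has an edge wherever the CA–CA
Euclidean distance is strictly below 10 Å (ties excluded); the threshold
follows the value established for CA-based contact maps in the
function-prediction literature. Two three-layer stacks run in parallel on
the raw 1280-dim node features:

* GCN: H' = ReLU(D̂^{-1/2}(A+I)D̂^{-1/2} H W), widths 1280 → 512 → 256 → 256;
* GAT: single head per layer, e_ij = LeakyReLU(aᵀ[Wh_i ∥ Wh_j]) with slope
  0.2, softmax-normalized over neighborhoods that include the self-loop,
  ReLU after aggregation, same widths.

Their outputs concatenate channel-wise to Y ∈ ℝ^{L×512}. Equal 256+256
halves are the natural split of the fixed 512 fused width; self-loops keep
isolated residues well-defined; both stacks see the raw embedding input.

**Fusion and head.** Bidirectional cross-attention with two heads and
d_k = 256 per head: in the sequence direction queries come from X and
keys/values from Y, and conversely. Per direction the heads' outputs are
concatenated and linearly projected (standard multihead closure). The two
directions concatenate per residue (L×1024), map to 512 with ReLU, mean-pool
exactly over residues, and a final linear layer plus element-wise sigmoid
yields independent per-term probabilities in GO-vocabulary order. Mean
pooling keeps the prediction invariant to residue permutation and to
duplication of the residue set; max-pool concatenation is not implemented
(channel concatenation + FC was chosen as the symmetric combination of the
two attention directions). Predicted probabilities are *not* propagated up
the DAG by default; `propagate_scores_max` offers post-hoc max-consistency.

**Attention records.** All four L×L row-stochastic attention maps
(2 directions × 2 heads) are retained from each forward pass. Residue
saliency is the mean attention a residue receives as a key (column mean)
averaged over heads and directions, min–max normalized to [0,1] (a constant
vector maps to all 0.5); query-side and single-direction averaging are
options, and raw averages are kept alongside. Agreement with binding-site
masks is an exact midrank ROC AUC (ties count ½).

## Autodiff engine

No deep-learning framework is used: the package contains a compact
tape-based reverse-mode autodiff engine over numpy arrays (`gofuse.autodiff`)
with the dozen primitives the model needs (matmul, broadcast arithmetic,
sigmoid/ReLU/LeakyReLU, exp/log/abs, fused stable softmax, reductions,
padding/slicing, concatenation). Convolutions are sums of shifted matmuls
over a zero-padded input; gradients flow only into parameter-dependent
subgraphs, so fixed inputs cost nothing on the backward pass. Gradient
correctness is checked against central finite differences in the test suite.
Parameters are float32, Glorot-uniform initialized from an explicit seeded
generator; all randomness in the package flows through `numpy.random`
generators seeded from user-supplied seeds, making training bit-reproducible
on a fixed machine.

## Ontology and labels

Only `is_a` and `part_of` relations are retained (CAFA convention).
Annotations are closed under the true-path rule before training and
evaluation; namespace roots are excluded everywhere (IC = 0, uninformative).
Information content is per-namespace:
P(t) = (#training proteins with t) / (#training proteins with ≥ 1 term in
t's namespace), IC(t) = −log₂ P(t). The per-namespace denominator keeps IC
comparable within an ontology; terms absent from the training split are
excluded from the vocabulary (their IC is undefined) with a logged count.
MF, BP and CC are evaluated independently.

## Metrics

CAFA-style, computed over a threshold grid τ ∈ {0.01, …, 1.00} (step 0.01,
configurable): protein-centric Fmax with precision averaged over proteins
having at least one prediction ≥ τ and recall over proteins with at least
one true term; IC-weighted Smin = min_τ √(ru² + mi²); micro-AUPR over all
(protein, term) pairs by the step-wise interpolation-free rule. The smallest
maximizing (minimizing) threshold is reported alongside Fmax (Smin). All
three implementations are verified against exhaustive brute-force oracles on
random small instances to 1e−9.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, no weight decay, no schedule) on the mean
per-term binary cross-entropy, computed in the numerically stable
logits form. Defaults follow the reference recipe: learning rate 1e−4,
batch size 64, up to 100 epochs, early stopping on validation loss with
patience 5, checkpoint at the lowest validation loss. Because proteins have
variable length, a batch is processed as gradient accumulation over
per-protein passes — identical in value and gradient to a padded masked
batch, since the loss is a mean of per-protein losses and pooling divides by
the true length. A NaN training loss aborts with diagnostics.

The model exposes an optional inverted-dropout rate (default 0.0) applied to
X, Y and the fused hidden layer during training only. The planted-data
experiments in this package (140 training proteins against ~25 M parameters)
train with dropout 0.5, learning rate 3e−4 and batch size 8: at that sample
size the reference recipe memorizes residue-level idiosyncrasies within a
few epochs, and small batches plus dropout are the standard remedy for
graph-attention models trained on little data. The reference defaults remain
the `TrainConfig` defaults.

## Synthetic data generator

The generator emulates the *contracts* of real data, not its statistics:

* **Structures** are self-avoiding CA chains with consecutive spacing
  exactly 3.8 Å (canonical backbone geometry) and a minimum non-consecutive
  distance of 3.0 Å, grown with a centroid-bias parameter. Each protein is
  drawn from one of two folding regimes — loose (bias −0.3) or compact
  (bias 1.5), 50/50 — whose contact-density distributions are cleanly
  separated (≲0.38 vs ≳0.46 at lengths 30–60), so a structural rule
  thresholded at density 0.40 is decidable from the graph alone.
* **Function labels** follow planted rules. Every leaf term of a toy
  single-namespace DAG (root → internal layer → leaves) owns a unique
  sequence 3-mer; a configurable fraction of leaves (default 25%) fire
  additionally when the contact density exceeds 0.40 (motif OR density).
  Leaf labels are evaluated on the final sequences and structures — so a
  rule-evaluating oracle classifier reproduces them exactly when label
  noise ε = 0 — then optionally flipped with probability ε, rebalanced so
  every leaf has ≥ 5% prevalence, and ancestor-closed.
* **Embeddings** are deterministic functions of (letter, position, seed):
  a per-letter base vector (scale 0.4), a positional sinusoid (0.2), and
  counter-seeded Gaussian noise (0.3); residues covered by a planted motif
  additionally receive the motif's sparse ±1 signature on 48 of 1280
  dimensions. This makes sequence rules learnable by the convolutional
  branch without any external language model.
* **Binding-site masks** mark the motif positions present in each sequence.

What passing tests on this generator show: the architecture can extract a
planted sequence signal through the gated-conv/attention path, a planted
structural signal through the GNN path, fuse them, and localize the
responsible residues. What they do not show: performance on real ESM-1b
embeddings (whose channels are correlated and position-entangled), on real
contact topologies, or on the label co-occurrence structure of real GO
corpora — the benchmark-scale numbers of the reference study are out of
reach without those inputs and GPU training.

## Problem sizes

The planted study runs on 200 proteins of 30–60 residues with 16 leaf terms
(70/15/15 train/val/test split), ≤ 50 epochs — chosen so a full train +
evaluate + saliency cycle completes in minutes on one CPU while leaving the
architecture at full width (1280/512/1536). The ablation re-run
(`freq_enabled=False`) uses a 10-epoch schedule; it is a structural check of
the switchable module, not a benchmark claim. Unit and oracle tests use
graphs of L ≤ 8 and metric instances of ≤ 10 proteins × 8 terms.

## Numerical choices and degenerate inputs

float32 parameters and activations (float64 for metrics and DCT utilities);
attention masking adds −1e30 before the fused stable softmax; BCE uses the
max(z,0) − zy + log(1+e^{−|z|}) form; min–max normalization maps constant
saliency vectors to 0.5; AUC uses midranks; Fmax reports 0 when nothing is
predicted at any threshold; isolated graph nodes are well-defined through
self-loops (Â = A + I guarantees degree ≥ 1); residues lacking a CA atom are
skipped and re-indexed (embeddings are computed on the CA-resolved
sequence), with the skip count logged; altloc ties resolve to conformer 'A';
HETATM residues are excluded except MSE (read as MET).

## Limitations

* Saliency uses the shared (not GO-term-conditioned) attention, so one
  score vector serves all predicted functions of a protein.
* The ESM-1b adapter consumes precomputed matrices only (HDF5/npy, BOS/EOS
  rows stripped when present); which model layer produced them is the
  caller's responsibility.
* Single chain per protein; no multimeric assemblies, Cβ or all-atom
  contact definitions, or distance-binned maps.
* CPU-only; wall-clock scales linearly in total residue count and is
  dominated by the 1280→512 convolutions.
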