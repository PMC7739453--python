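# Methods

## The model

`gcnppi` predicts whether two proteins physically interact. Each protein
gets one representation vector built from two channels:

**Sequence channel.** The amino-acid sequence is one-hot encoded over the
20 standard residues (alphabetical order A, C, D, ..., Y) into a fixed
`L x 20` binary matrix. Sequences shorter than `L` are zero-padded at the
front; longer ones keep only their last `L` residues (front truncation).
The matrix is flattened row-major into a length `L*20` vector. Non-standard
residue letters (B, J, O, U, X, Z) are accepted on input but encode as an
all-zero row, indistinguishable from padding: the 20-row identity matrix
used for encoding has no 21st row, and zero is the least committal choice.

**Position channel.** The PPI network is an unweighted, undirected graph
over all proteins in the dataset (transductive: the node set is fixed up
front). Edges come exclusively from the *positive pairs of the current
training fold*. One graph-convolution layer embeds every node:

    X1 = σ( D̃⁻¹ Ã X0 W0 ),   Ã = A + I_N,   D̃_ii = Σ_j Ã_ij

with `X0 = I_N` (each protein one-hot over proteins), `W0` an `N x f`
trainable matrix and σ the rectifier. Because `X0` is the identity the
product simplifies to `σ(D̃⁻¹ Ã W0)`: row *i* is the degree-normalized
average of `W0` rows over node *i*'s closed neighborhood. Normalization is
the row-stochastic `D̃⁻¹Ã` (random-walk), not the symmetric variant. The
self-connection guarantees `D̃_ii ≥ 1`, so a protein with no positive
training edge still has a well-defined row: the activation of its own `W0`
row.

`W0` is initialized uniformly in ±1: its input is one-hot, so each node
activates exactly one row and the effective fan-in is 1. Before the
embedding block is concatenated with the sequence block it is scaled to
unit RMS (over all entries, with the exact gradient propagated through
the normalizer). Without this, the neighborhood-averaged embedding
entries are an order of magnitude smaller than the {0,1} sequence
features, the first dense layer's position weights receive
correspondingly small gradients, and training settles into a
sequence-only shortcut that never exploits the graph — a measurable
pathology, not a hypothetical one. The normalization keeps the two
channels on comparable scales throughout training regardless of how
`W0` evolves, and can be disabled per run.

**Classifier.** The two proteins of a pair pass through two structurally
identical but *separately parameterized* branch networks: four dense
layers of widths 256, 128, 64, 32, each followed by batch normalization
(affine → normalize → rectifier) and dropout (p = 0.5 after the
activation). The two 32-vectors are concatenated and a joint head (dense
widths 8 then 2, softmax) produces the interaction probability (second
softmax component). Classification thresholds at 0.5, ties counting as
positive. Because branches do not share weights, `predict(a, b)` need not
equal `predict(b, a)`; pairs are presented in stored order, and an
optional flag augments training with swapped copies (off by default).

**Training.** All parameters — `W0` and the dense network — are updated
jointly by plain SGD against the softmax cross-entropy of the pair label.
The gradient reaches `W0` through the position block of both pair members:
`dW0 = Mᵀ (dX1 ⊙ 1[pre > 0])` with `M = D̃⁻¹Ã`. The layers are written in
NumPy with explicit backpropagation; gradients are checked against central
finite differences (relative tolerance 1e-4) in the test suite, including
the path through batch normalization and into `W0`.

## Cross-validation and leakage

Folds are stratified by label at the pair level (a protein may appear in
both train and test pairs, matching the pair-count bookkeeping of the
benchmarks; a stricter protein-level split is available). For every fold
the graph is rebuilt from that fold's positive training pairs only, so the
adjacency is bit-identical whether or not test pairs exist in the dataset
— this is asserted as a test. Evaluation runs in deterministic evaluation
mode: dropout off, batch normalization on running statistics.

The summary reports both the mean over per-fold metrics and the
pooled-count metrics over all test predictions, since the two can differ.

## Metrics

Precision = TP/(TP+FP), recall = TP/(TP+FN), accuracy =
(TP+TN)/total, computed from thresholded counts. When a denominator is
zero the metric is reported as undefined (`None`/`NA`), never silently 0.
The precision–recall curve sweeps every distinct score as a `>=`
threshold; the area (auPR) is the step-wise rectangle sum
`Σ (R_i − R_{i−1}) P_i` with `R_0 = 0`. Linear interpolation of PR curves
is known to overestimate the area and is not used. The sweep is tested
against an independent exhaustive-threshold enumeration.

## Synthetic data

The generator plants interaction signal in both channels so the feature
ablation is testable without external downloads:

- **Topology:** a stochastic block model. Proteins are split evenly into
  `n_groups` latent groups; a same-group pair is positive with
  `p_within`, a cross-group pair with `p_between`. Neighborhood averaging
  — exactly what the GCN computes — exposes this structure.
- **Both channels predict the same latent variable** (group identity), so
  the classifier's task is a group-match decision readable from either
  channel, and combining them is informative exactly as intended.
- **Sequence:** each group draws a `motif_length`-residue motif over its
  own small, disjoint sub-alphabet (the 20 letters shuffled and chunked),
  inserted at a uniform-random position into a member's otherwise
  uniform-random sequence with probability `motif_insertion_prob`. Group
  membership is then readable from residue composition alone, which a
  dense network on flattened one-hot input can learn.

Defaults (the study conditions): 60 proteins, 2 groups, sequences 50–80
residues, motif length 10 inserted with probability 0.9, `p_within` 0.9,
`p_between` 0.05, 800 emitted pairs at prevalence 0.5. The emitted list
hits the requested prevalence within one pair; negatives are drawn
uniformly from non-interacting pairs. Everything is reproducible from one
seed. The group count and pair count are data-sufficiency choices: the
positive-pair pool grows with group size (two groups of 30 offer ~870
within-group pairs against ~510 for three groups of 20), and with too few
labeled pairs the pair-level decision rule is under-determined for any
learner — an independently trained multilayer-perceptron probe hits the
same ceiling — which starves the sequence channel in particular and
breaks the premise that both channels are individually informative.

What the generator does **not** emulate: Uniprot-scale sequence lengths
and composition biases, realistic PPI degree distributions (scale-free
hubs), experimental false positives, or homology between proteins.
Passing tests therefore demonstrate that the pipeline's mechanics and its
two-channel design behave as intended under controlled signal — not that
the reported benchmark numbers transfer to real proteomes.

## The desk-scale study configuration

Cross-validated training at the full reference settings (L = 850, widths
256/128/64/32, dropout 0.5) is sized for benchmarks with ~10⁴ pairs and
long sequences. The synthetic study runs a width-scaled instance of the
same architecture (`experiment.desk_scale_config`): L = 80 (the generator
emits 50–80 residues, so nothing is truncated), embedding width f = 16,
branch widths (64, 32, 16, 8), joint head (8, 2), 200 epochs of batch-32
SGD at the stated learning rate 0.01, single precision. Dropout is
lowered to 0.1: dropping half of an 8-unit layer removes most of its
representation, so the full-scale rate of 0.5 is disproportionately
destructive at these widths (empirically it stalls optimization entirely,
while the scaled model trains to high accuracy without it). Library
defaults are unchanged — the scaled settings apply only to the synthetic
study and are reported as such.

Under these conditions the combined representation reaches a 5-fold mean
accuracy far above chance across seeds, the combined arm is at least as
good as the better single channel, and label-permuted data collapses to
0.5 — the qualitative ablation pattern, reproduced by
`scripts/acceptance.py`.

## Numerical choices

- Parameter initialization: uniform in ±1/√fan-in for dense layers
  (fan-in 1, hence ±1, for the one-hot-driven `W0`), from one seeded
  generator per fold (seed derived from the run seed and fold index).
- The embedding block is scaled to unit RMS before concatenation
  (`normalize_embedding`, on by default), with the exact gradient of the
  normalizer used during training.
- Batch normalization: ε = 1e-5, running-statistics momentum 0.1, biased
  batch variance; evaluation uses running statistics.
- Dropout is inverted (scaling by 1/(1−p) at train time).
- Batches with a single sample are skipped (batch statistics undefined).
- Cross-entropy is clamped with a 1e-12 floor inside the logarithm.
- float32 vs float64 is a run option; the default is float64, the
  desk-scale study uses float32 for speed.

## Limitations

- Transductive only: a protein absent from the dataset's node set has no
  embedding; inductive generalization to unseen proteins is out of scope.
- The branch networks see flattened fixed-length one-hot input, so the
  sequence channel is position-sensitive; motif detection relies on
  composition rather than translation invariance (no convolutions, by
  design).
- Pair-level cross-validation shares proteins between train and test
  pairs; protein-level splitting is stricter and available behind a flag.
- The external benchmark deposit is not bundled; its integrity checks run
  only when the deposit is supplied locally.
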