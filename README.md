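# gcnppi

Protein–protein interaction (PPI) prediction that combines **what a
protein is made of** with **where it sits in the interaction network**.

Most sequence-based PPI predictors represent a protein only by its amino
acids. `gcnppi` additionally embeds each protein's *position* in the PPI
network graph with a graph convolutional network (GCN) and feeds both
channels to a twin-branch classifier. The package provides the full
pipeline — data loading, encoding, graph embedding, training,
leakage-safe cross-validation, precision–recall evaluation — plus a
synthetic-data generator that plants interaction signal in both channels
so everything is testable offline.

## Model

Each protein `p` is represented by the concatenation of:

1. **Sequence channel** — the one-hot encoding of its amino-acid
   sequence over the 20 standard residues, as a fixed `L × 20` matrix
   (default `L = 850`; front zero-padding, front truncation), flattened
   to a length-`L·20` vector.
2. **Position channel** — row `p` of the one-layer GCN embedding

   `X₁ = σ( D̃⁻¹ Ã X₀ W₀ )`,  `Ã = A + I_N`,  `D̃ᵢᵢ = Σⱼ Ãᵢⱼ`

   where `A` is the adjacency over the *positive training pairs only*
   (no test-set leakage), `X₀ = I_N` (one-hot protein features), `W₀` an
   `N × f` trainable matrix and σ the rectifier.

A pair `(a, b)` is scored by two structurally identical, separately
parameterized branch networks (dense widths 256–128–64–32, each with
batch normalization and dropout 0.5) whose outputs are concatenated into
a joint head (widths 8, 2) ending in a softmax; the second component is
the interaction probability. Everything — `W₀` included — is trained
jointly by SGD (learning rate 0.01) on the pair cross-entropy.

Evaluation reports precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, accuracy
`(TP+TN)/total`, and the area under the precision–recall curve computed
by a step-wise sweep over all score thresholds.

See `docs/methods.md` for assumptions, parameter rationale and
limitations.

## Worked example

Generate a synthetic benchmark (60 proteins in 2 latent interaction
groups; group-specific sequence motifs + block-structured topology; 800
balanced labeled pairs) and run the three-arm feature ablation with
5-fold cross-validation:

```sh
cat > desk.yaml <<'YAML'
train:
  epochs: 200
  L: 80
  f: 16
  branch_widths: [64, 32, 16, 8]
  joint_widths: [8, 2]
  dropout_p: 0.1
  batch_size: 32
  dtype: float32
YAML
gcnppi synth --out data --seed 1
gcnppi ablation --dataset-dir data --config desk.yaml --k 5 --seed 1 \
    --out results
```

which prints (numbers from this exact invocation, using the scaled
desk-size network of `docs/methods.md`; about 3 minutes on one CPU):

```
[combined] fold-mean accuracy 0.9088
[sequence_only] fold-mean accuracy 0.9063
[position_only] fold-mean accuracy 0.9150
```

and `results/ablation.tsv` holds the full table:

```
mode            precision  recall  accuracy  auPR
combined        0.9027     0.9175  0.9088    0.8995
sequence_only   0.9018     0.9125  0.9063    0.8940
position_only   0.9113     0.9200  0.9150    0.8976
```

Reading: on data where group membership is visible in *both* the
sequences and the graph, either channel alone supports accurate
prediction, and the combined representation performs on par with the
better channel — the qualitative ablation pattern the method is built
around. Per-fold metrics and PR-curve points are written alongside.

With real data, point `--dataset-dir` at a directory containing
`proteins.fasta` and `pairs.tsv` (tab- or space-separated
`id_a id_b label`, `#` comments). `gcnppi verify --dataset-dir ...`
checks a loaded dataset against the published composition of the yeast
core benchmark (11188 pairs, 5594/5594, all sequences ≥ 50 residues).

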