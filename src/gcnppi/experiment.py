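"""Training, leakage-safe cross-validation, metrics and the ablation study.

The model is trained end-to-end by stochastic gradient descent: the GCN
weight matrix ``W0`` and all dense-network parameters receive gradients
from the pair-classification cross-entropy.  For every cross-validation
fold the PPI graph is rebuilt from THAT fold's positive training pairs
only, so the adjacency used for position embeddings never sees test
pairs.

Three ablation arms share one architecture: ``combined`` uses both
feature blocks, ``sequence_only`` zeroes the position block of every
representation, and ``position_only`` zeroes the sequence block.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data_io import Dataset, InteractionPair
from .interaction_model import BRANCH_WIDTHS, JOINT_WIDTHS, PairedModel
from .network_embedding import GCNLayer, build_graph, init_gcn_layer, \
    normalized_adjacency
from .sequence_encoding import DEFAULT_LENGTH, encode_dataset

MODES = ("combined", "sequence_only", "position_only")


class ConfigurationError(ValueError):
    """Raised for an invalid run configuration, naming the offending key."""


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the reference settings: SGD at learning rate 0.01,
    dropout 0.5, sequence length cap ``L`` = 850, one GCN layer.  The
    embedding width ``f`` and the epoch/batch sizes are free choices.
    """

    learning_rate: float = 0.01
    dropout_p: float = 0.5
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    mode: str = "combined"
    L: int = DEFAULT_LENGTH
    f: int = 128
    branch_widths: tuple[int, ...] = BRANCH_WIDTHS
    joint_widths: tuple[int, ...] = JOINT_WIDTHS
    threshold: float = 0.5
    augment_swapped_pairs: bool = False
    normalize_embedding: bool = True
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError(
                f"learning_rate must be > 0, got {self.learning_rate}")
        if self.mode not in MODES:
            raise ConfigurationError(
                f"mode must be one of {MODES}, got {self.mode!r}")
        if self.epochs < 0:
            raise ConfigurationError(f"epochs must be >= 0, got {self.epochs}")
        if self.batch_size < 2:
            raise ConfigurationError(
                f"batch_size must be >= 2, got {self.batch_size}")
        if self.L < 1:
            raise ConfigurationError(f"L must be >= 1, got {self.L}")
        if self.f < 1:
            raise ConfigurationError(f"f must be >= 1, got {self.f}")
        if self.dtype not in ("float32", "float64"):
            raise ConfigurationError(
                f"dtype must be float32 or float64, got {self.dtype!r}")

    @property
    def np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64


@dataclass(frozen=True)
class FoldSplit:
    """A stratified partition of pairs into k folds."""

    k: int
    assignments: np.ndarray  # fold index per pair, aligned with the pair list

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


def kfold_split(pairs: Sequence[InteractionPair], k: int,
                seed: int) -> FoldSplit:
    """Deterministic stratified k-fold assignment at the pair level."""
    labels = np.array([p.label for p in pairs])
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if k < 2 or k > min(n_pos, n_neg):
        raise ConfigurationError(
            f"k={k} out of range for {n_pos} positive / {n_neg} negative pairs"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(pairs), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(labels, labels)):
        assignments[test_idx] = fold
    return FoldSplit(k=k, assignments=assignments)


def protein_level_split(pairs: Sequence[InteractionPair], k: int,
                        seed: int) -> FoldSplit:
    """Stricter alternative split: a protein's pairs all share one fold.

    Proteins are shuffled into k groups; a pair is assigned to the fold of
    its first protein.  Not stratified — offered for leakage-sensitive
    analyses, not used by default.
    """
    rng = np.random.default_rng(seed)
    proteins = sorted({pid for p in pairs for pid in (p.id_a, p.id_b)})
    order = rng.permutation(len(proteins))
    fold_of = {proteins[j]: i % k for i, j in enumerate(order)}
    assignments = np.array([fold_of[p.id_a] for p in pairs], dtype=np.int64)
    return FoldSplit(k=k, assignments=assignments)


# -- metrics ---------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts, threshold metrics, and the PR curve with its area.

    ``precision`` / ``recall`` are ``None`` when their denominator is zero
    (no predicted positives, resp. no true positives) rather than silently
    zero.  ``pr_curve`` holds (recall, precision) points at every distinct
    score threshold; ``auPR`` is their step-wise rectangle area.
    """

    counts: ConfusionCounts
    precision: float | None
    recall: float | None
    accuracy: float
    pr_curve: np.ndarray
    auPR: float | None


def pr_curve_sweep(scores: np.ndarray, labels: np.ndarray,
                   ) -> tuple[np.ndarray, float | None]:
    """PR points over all distinct score thresholds, plus the step area.

    At threshold t, every pair with score >= t is predicted positive.
    Points are ordered by increasing recall; the area is the rectangle sum
    sum_i (R_i - R_{i-1}) * P_i with R_0 = 0 (precision held constant
    between consecutive recall points — linear interpolation of PR curves
    overestimates and is not used).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        return np.empty((0, 2)), None
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tp_cum = np.cumsum(labels[order])
    fp_cum = np.cumsum(1 - labels[order])
    # last occurrence of each distinct score = the >= threshold cut
    last = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(scores) - 1]
    precision = tp_cum[last] / (tp_cum[last] + fp_cum[last])
    recall = tp_cum[last] / n_pos
    area = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return np.column_stack([recall, precision]), area


def evaluate(scores: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> EvalReport:
    """Threshold metrics plus the PR curve for one set of pair scores.

    Ties at the threshold classify as positive (score >= threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("one score per labeled pair is required")
    pred = scores >= threshold
    pos = labels == 1
    counts = ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )
    precision = (counts.tp / (counts.tp + counts.fp)
                 if counts.tp + counts.fp > 0 else None)
    recall = (counts.tp / (counts.tp + counts.fn)
              if counts.tp + counts.fn > 0 else None)
    accuracy = (counts.tp + counts.tn) / counts.total
    curve, area = pr_curve_sweep(scores, labels)
    return EvalReport(counts=counts, precision=precision, recall=recall,
                      accuracy=accuracy, pr_curve=curve, auPR=area)


# -- training --------------------------------------------------------------

@dataclass
class TrainedFold:
    """Everything produced by training on one fold."""

    model: PairedModel
    gcn: GCNLayer
    graph: object
    epoch_losses: list[float] = field(default_factory=list)


def _feature_blocks(dataset: Dataset, config: TrainConfig) -> np.ndarray:
    """N x (L*20) matrix of flattened one-hot sequence features."""
    return encode_dataset(dataset.records, L=config.L)


def _assemble(seq_block: np.ndarray, X1: np.ndarray, idx: np.ndarray,
              mode: str) -> np.ndarray:
    """Per-protein representations for the given node indices.

    The representation width is L*20 + f in every mode; the inactive
    block is zeroed so the three ablation arms share one architecture.
    """
    seq = seq_block[idx]
    pos = X1[idx]
    if mode == "sequence_only":
        pos = np.zeros_like(pos)
    elif mode == "position_only":
        seq = np.zeros_like(seq)
    return np.concatenate([seq, pos], axis=1)


def train_fold(dataset: Dataset, split: FoldSplit, fold: int,
               config: TrainConfig) -> TrainedFold:
    """Train the pair classifier (and W0, jointly) on one training fold.

    The PPI graph is rebuilt from this fold's positive training pairs
    only.  Deterministic given ``config.seed`` and the fold index.
    """
    train_idx = split.train_indices(fold)
    if train_idx.size == 0:
        raise ConfigurationError(f"training fold {fold} is empty")
    train_pairs = [dataset.pairs[i] for i in train_idx]

    node_ids = dataset.node_ids
    node_index = {pid: i for i, pid in enumerate(node_ids)}
    graph = build_graph(train_pairs, node_ids)
    dtype = config.np_dtype
    M = normalized_adjacency(graph).astype(dtype)

    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(fold)]))
    gcn = init_gcn_layer(len(node_ids), config.f, rng)
    gcn.W0 = gcn.W0.astype(dtype)
    d_in = config.L * 20 + config.f
    model = PairedModel(d_in, config.branch_widths, config.joint_widths,
                        dropout_p=config.dropout_p, rng=rng, dtype=dtype)

    seq_block = _feature_blocks(dataset, config).astype(dtype)

    a_idx = np.array([node_index[p.id_a] for p in train_pairs])
    b_idx = np.array([node_index[p.id_b] for p in train_pairs])
    y = np.array([p.label for p in train_pairs])
    if config.augment_swapped_pairs:
        a_idx, b_idx = np.r_[a_idx, b_idx], np.r_[b_idx, a_idx]
        y = np.r_[y, y]

    from .nn import sgd_step, softmax_cross_entropy

    n = len(y)
    seq_width = config.L * 20
    train_pos = config.mode != "sequence_only"
    losses: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            if batch.size < 2:
                continue  # batch statistics are undefined for one sample
            # forward through the GCN (training mode: keep the ReLU mask)
            pre = M @ gcn.W0
            H = np.maximum(pre, 0.0)
            if config.normalize_embedding:
                # unit-RMS embedding block: the position channel enters
                # the classifier on the same scale as the {0,1} sequence
                # features, whatever the current magnitude of W0
                r = np.sqrt(np.mean(H * H) + 1e-12)
                X1 = H / r
            else:
                X1 = H
            rep_a = _assemble(seq_block, X1, a_idx[batch], config.mode)
            rep_b = _assemble(seq_block, X1, b_idx[batch], config.mode)
            model.zero_grad()
            logits = model.forward(rep_a, rep_b, training=True)
            loss, dlogits = softmax_cross_entropy(logits, y[batch])
            d_a, d_b = model.backward(dlogits)
            if train_pos:
                dX1 = np.zeros_like(X1)
                np.add.at(dX1, a_idx[batch], d_a[:, seq_width:])
                np.add.at(dX1, b_idx[batch], d_b[:, seq_width:])
                if config.normalize_embedding:
                    # d/dH of H/r with scalar r = RMS(H)
                    dH = (dX1 - X1 * np.mean(dX1 * X1)) / r
                else:
                    dH = dX1
                dW0 = M.T @ (dH * (pre > 0))
                gcn.W0 -= config.learning_rate * dW0
            sgd_step(model.modules, config.learning_rate)
            batch_losses.append(loss)
        if batch_losses:
            losses.append(float(np.mean(batch_losses)))
    return TrainedFold(model=model, gcn=gcn, graph=graph,
                       epoch_losses=losses)


def score_pairs(trained: TrainedFold, dataset: Dataset,
                pairs: Sequence[InteractionPair],
                config: TrainConfig) -> np.ndarray:
    """Interaction probabilities for *pairs* in evaluation mode."""
    node_index = {pid: i for i, pid in enumerate(dataset.node_ids)}
    from .network_embedding import gcn_embed
    X1 = gcn_embed(trained.graph, trained.gcn).astype(config.np_dtype)
    if config.normalize_embedding:
        X1 = X1 / np.sqrt(np.mean(X1 * X1) + 1e-12)
    seq_block = _feature_blocks(dataset, config).astype(config.np_dtype)
    a_idx = np.array([node_index[p.id_a] for p in pairs])
    b_idx = np.array([node_index[p.id_b] for p in pairs])
    rep_a = _assemble(seq_block, X1, a_idx, config.mode)
    rep_b = _assemble(seq_block, X1, b_idx, config.mode)
    from .interaction_model import predict_pair
    return predict_pair(rep_a, rep_b, trained.model, training_mode=False)[:, 1]


# -- cross-validation ------------------------------------------------------

@dataclass
class CrossValResult:
    """Per-fold evaluation reports plus fold-mean and pooled summaries."""

    fold_reports: list[EvalReport]
    mean_metrics: dict[str, float]
    pooled_metrics: dict[str, float]
    fold_scores: list[np.ndarray] = field(default_factory=list)
    fold_labels: list[np.ndarray] = field(default_factory=list)


def _mean_ignoring_none(values) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def cross_validate(dataset: Dataset, config: TrainConfig,
                   k: int) -> CrossValResult:
    """k-fold cross-validation with a leakage-safe graph per fold.

    The summary reports both the mean over per-fold metrics and the
    pooled-count metrics computed from all test predictions at once.
    """
    split = kfold_split(dataset.pairs, k, config.seed)
    reports: list[EvalReport] = []
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for fold in range(k):
        trained = train_fold(dataset, split, fold, config)
        test_pairs = [dataset.pairs[i] for i in split.test_indices(fold)]
        scores = score_pairs(trained, dataset, test_pairs, config)
        labels = np.array([p.label for p in test_pairs])
        reports.append(evaluate(scores, labels, config.threshold))
        all_scores.append(scores)
        all_labels.append(labels)
    mean_metrics = {
        "precision": _mean_ignoring_none(r.precision for r in reports),
        "recall": _mean_ignoring_none(r.recall for r in reports),
        "accuracy": float(np.mean([r.accuracy for r in reports])),
        "auPR": _mean_ignoring_none(r.auPR for r in reports),
    }
    pooled = evaluate(np.concatenate(all_scores), np.concatenate(all_labels),
                      config.threshold)
    pooled_metrics = {
        "precision": pooled.precision,
        "recall": pooled.recall,
        "accuracy": pooled.accuracy,
        "auPR": pooled.auPR,
    }
    return CrossValResult(fold_reports=reports, mean_metrics=mean_metrics,
                          pooled_metrics=pooled_metrics,
                          fold_scores=all_scores, fold_labels=all_labels)


def run_ablation(dataset: Dataset, config: TrainConfig, k: int,
                 ) -> dict[str, CrossValResult]:
    """Cross-validate the three feature arms under one shared setup."""
    results = {}
    for mode in MODES:
        results[mode] = cross_validate(
            dataset, dataclasses.replace(config, mode=mode), k)
    return results


def permute_labels(dataset: Dataset, seed: int) -> Dataset:
    """Dataset copy with pair labels randomly permuted (chance-floor control)."""
    rng = np.random.default_rng(seed)
    labels = rng.permutation([p.label for p in dataset.pairs])
    pairs = [InteractionPair(p.id_a, p.id_b, int(lbl))
             for p, lbl in zip(dataset.pairs, labels)]
    return Dataset(records=dataset.records, pairs=pairs,
                   name=dataset.name + "-permuted")


# -- desk-scale study ------------------------------------------------------

def desk_scale_config(seed: int, mode: str = "combined") -> TrainConfig:
    """Training configuration of the scaled-down synthetic study.

    The reference settings keep the stated learning rate (0.01) but scale
    the rest to desk size: sequences are capped at L = 80 (the generator
    emits 50-80 residues), the embedding width is 16, and the branch
    widths shrink to (64, 32, 16, 8).  Dropout is lowered to 0.1 — at
    widths this small, dropping half of an 8-unit layer removes most of
    the representation, so the full-scale rate of 0.5 would be
    disproportionately destructive.  Single-precision arithmetic keeps
    the run fast; the classification outcome is insensitive to it.
    """
    return TrainConfig(learning_rate=0.01, dropout_p=0.1, epochs=200,
                       batch_size=32, seed=seed, mode=mode, L=80, f=16,
                       branch_widths=(64, 32, 16, 8), joint_widths=(8, 2),
                       dtype="float32")


def desk_scale_dataset(seed: int):
    """The synthetic dataset of the desk-scale study (generator defaults)."""
    from .synthetic_data import SyntheticConfig, generate
    return generate(SyntheticConfig(seed=seed))


# -- result files ----------------------------------------------------------

def write_results(result: CrossValResult, out_dir: str | Path,
                  prefix: str = "") -> None:
    """Write per-fold metrics, summary and PR points as delimited text."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"{prefix}_" if prefix else ""

    def fmt(v):
        return "NA" if v is None else f"{v:.6f}"

    with open(out_dir / f"{tag}folds.tsv", "w") as fh:
        fh.write("fold\tTP\tTN\tFP\tFN\tprecision\trecall\taccuracy\tauPR\n")
        for i, r in enumerate(result.fold_reports):
            c = r.counts
            fh.write(f"{i}\t{c.tp}\t{c.tn}\t{c.fp}\t{c.fn}\t"
                     f"{fmt(r.precision)}\t{fmt(r.recall)}\t"
                     f"{fmt(r.accuracy)}\t{fmt(r.auPR)}\n")
    with open(out_dir / f"{tag}summary.tsv", "w") as fh:
        fh.write("statistic\tprecision\trecall\taccuracy\tauPR\n")
        for label, m in (("fold_mean", result.mean_metrics),
                         ("pooled", result.pooled_metrics)):
            fh.write(f"{label}\t{fmt(m['precision'])}\t{fmt(m['recall'])}\t"
                     f"{fmt(m['accuracy'])}\t{fmt(m['auPR'])}\n")
    for i, r in enumerate(result.fold_reports):
        with open(out_dir / f"{tag}pr_fold{i}.tsv", "w") as fh:
            fh.write("recall\tprecision\n")
            for rec, prec in r.pr_curve:
                fh.write(f"{rec:.6f}\t{prec:.6f}\n")
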