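"""Twin-branch pair classifier over combined sequence + position features.

Each protein is represented by the concatenation of its flattened one-hot
sequence matrix (length ``L * 20``) and its GCN position-embedding row
(length ``f``).  The two proteins of a pair pass through two structurally
identical but separately parameterized branch networks (four dense layers
of widths 256, 128, 64, 32, each followed by batch normalization and
dropout); their 32-dimensional outputs are concatenated and mapped by a
joint head (dense widths 8 and 2) to a 2-way softmax, whose second entry
is the interaction probability.

Because the branches do not share weights, ``predict(a, b)`` need not
equal ``predict(b, a)``; pairs are presented in stored order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm1d, Dropout, Linear, ReLU, Sequential, softmax)

#: Default branch hidden widths; the joint head adds widths 8 and 2.
BRANCH_WIDTHS = (256, 128, 64, 32)
JOINT_WIDTHS = (8, 2)


def combine_representation(seq_features: np.ndarray,
                           pos_row: np.ndarray) -> np.ndarray:
    """Concatenate flattened sequence features with a position-embedding row."""
    if seq_features.ndim != 1 or pos_row.ndim != 1:
        raise ValueError("representation inputs must be 1-D vectors")
    return np.concatenate([seq_features, pos_row])


def make_branch(d_in: int, widths: tuple[int, ...], dropout_p: float,
                rng: np.random.Generator, dtype=np.float64) -> Sequential:
    """Dense -> batch-norm -> rectifier -> dropout, repeated per width."""
    layers = []
    prev = d_in
    for w in widths:
        layers += [Linear(prev, w, rng, dtype), BatchNorm1d(w, dtype=dtype),
                   ReLU(), Dropout(dropout_p, rng)]
        prev = w
    return Sequential(layers)


class PairedModel:
    """Twin branch networks plus a joint softmax head.

    Parameters
    ----------
    d_in
        Per-protein representation length, ``L * 20 + f``.
    branch_widths, joint_widths
        Dense-layer output widths; defaults (256, 128, 64, 32) and (8, 2).
    dropout_p
        Drop probability applied after every branch activation.
    rng
        Source of randomness for initialization and dropout masks.
    """

    def __init__(self, d_in: int,
                 branch_widths: tuple[int, ...] = BRANCH_WIDTHS,
                 joint_widths: tuple[int, ...] = JOINT_WIDTHS,
                 dropout_p: float = 0.5,
                 rng: np.random.Generator | None = None,
                 dtype=np.float64):
        if joint_widths[-1] != 2:
            raise ValueError("the joint head must end in 2 output units")
        rng = rng if rng is not None else np.random.default_rng()
        self.d_in = d_in
        self.branch_widths = tuple(branch_widths)
        self.joint_widths = tuple(joint_widths)
        self.dropout_p = dropout_p
        self.dtype = dtype
        self.branch_a = make_branch(d_in, self.branch_widths, dropout_p, rng,
                                    dtype)
        self.branch_b = make_branch(d_in, self.branch_widths, dropout_p, rng,
                                    dtype)
        joint_layers = []
        prev = 2 * self.branch_widths[-1]
        for i, w in enumerate(self.joint_widths):
            joint_layers.append(Linear(prev, w, rng, dtype))
            if i < len(self.joint_widths) - 1:
                joint_layers.append(ReLU())
            prev = w
        self.joint = Sequential(joint_layers)
        self._h_width = self.branch_widths[-1]

    # -- forward / backward ------------------------------------------------

    def forward(self, rep_a: np.ndarray, rep_b: np.ndarray,
                training: bool) -> np.ndarray:
        """Logits (n, 2) for a batch of pairs."""
        if rep_a.shape[1] != self.d_in or rep_b.shape[1] != self.d_in:
            raise ValueError(
                f"representation width {rep_a.shape[1]} does not match the "
                f"model input width {self.d_in}"
            )
        h_a = self.branch_a.forward(rep_a, training)
        h_b = self.branch_b.forward(rep_b, training)
        return self.joint.forward(np.concatenate([h_a, h_b], axis=1), training)

    def backward(self, dlogits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backpropagate; returns gradients w.r.t. the two representations."""
        dh = self.joint.backward(dlogits)
        d_a = self.branch_a.backward(dh[:, :self._h_width])
        d_b = self.branch_b.backward(dh[:, self._h_width:])
        return d_a, d_b

    # -- bookkeeping -------------------------------------------------------

    @property
    def modules(self):
        return [self.branch_a, self.branch_b, self.joint]

    def zero_grad(self) -> None:
        for m in self.modules:
            m.zero_grad()

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for tag, m in zip(("a", "b", "joint"), self.modules):
            for name, p in m.parameters().items():
                out[f"{tag}.{name}"] = p
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All arrays needed to reproduce evaluation, incl. running stats."""
        out = dict(self.parameters())
        for tag, m in zip(("a", "b", "joint"), self.modules):
            for i, layer in enumerate(m.layers):
                if isinstance(layer, BatchNorm1d):
                    out[f"{tag}.{i}.running_mean"] = layer.running_mean
                    out[f"{tag}.{i}.running_var"] = layer.running_var
        return out


def predict_pair(rep_a: np.ndarray, rep_b: np.ndarray, model: PairedModel,
                 training_mode: bool = False) -> np.ndarray:
    """Softmax probability vector(s) for one pair or a batch of pairs.

    Entry 1 (the second component) is the interaction probability.
    """
    single = rep_a.ndim == 1
    if single:
        rep_a, rep_b = rep_a[None, :], rep_b[None, :]
    probs = softmax(model.forward(rep_a, rep_b, training_mode))
    return probs[0] if single else probs


# -- checkpointing ---------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters embedded in a checkpoint."""

    d_in: int
    branch_widths: tuple[int, ...]
    joint_widths: tuple[int, ...]
    dropout_p: float


def save_checkpoint(path, model: PairedModel, gcn_W0: np.ndarray,
                    config: dict) -> None:
    """Serialize model + GCN weights + run configuration to one file."""
    spec = {
        "d_in": model.d_in,
        "branch_widths": list(model.branch_widths),
        "joint_widths": list(model.joint_widths),
        "dropout_p": model.dropout_p,
        "config": config,
    }
    arrays = {f"model/{k}": v for k, v in model.state_arrays().items()}
    arrays["gcn/W0"] = gcn_W0
    np.savez(path, __spec__=json.dumps(spec), **arrays)


def load_checkpoint(path) -> tuple[PairedModel, np.ndarray, dict]:
    """Restore a model, its GCN weights and the embedded configuration."""
    data = np.load(path, allow_pickle=False)
    spec = json.loads(str(data["__spec__"]))
    model = PairedModel(
        d_in=spec["d_in"],
        branch_widths=tuple(spec["branch_widths"]),
        joint_widths=tuple(spec["joint_widths"]),
        dropout_p=spec["dropout_p"],
        rng=np.random.default_rng(0),
    )
    state = model.state_arrays()
    for key in data.files:
        if key.startswith("model/"):
            state[key[len("model/"):]][...] = data[key]
    return model, data["gcn/W0"], spec["config"]
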