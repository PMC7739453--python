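"""PPI network graph construction and GCN position embedding.

The PPI network is an unweighted, undirected graph whose nodes are all
proteins of the dataset and whose edges are the POSITIVE pairs of the
current training fold only — test pairs never touch the adjacency, which
is what makes cross-validation leakage-safe in this transductive setting.

A single graph-convolution layer embeds every node:

    X1 = sigma( D~^-1 A~ X0 W0 ),   A~ = A + I,   D~_ii = sum_j A~_ij

with X0 the N x N identity (each protein one-hot over proteins), so the
product simplifies to ``sigma(D~^-1 A~ W0)``: row i of X1 is the
degree-normalized average of W0 rows over node i's closed neighborhood,
passed through the activation (rectifier by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .data_io import InteractionPair, IntegrityError


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def identity(x: np.ndarray) -> np.ndarray:
    return x


@dataclass
class PPIGraph:
    """Node set, positive-edge set and self-connected adjacency structures."""

    node_ids: list[str]
    edges: set[frozenset]
    A: np.ndarray = field(repr=False)
    A_tilde: np.ndarray = field(repr=False)
    D_tilde: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Diagonal of D~ (closed-neighborhood degrees, every entry >= 1)."""
        return np.diag(self.D_tilde)


def build_graph(train_pairs: Iterable[InteractionPair],
                node_ids: Sequence[str]) -> PPIGraph:
    """Build the undirected PPI graph from positive training pairs.

    Every node gets a self-connection; negative pairs contribute nothing;
    duplicate positive pairs collapse to a single edge.  Nodes absent from
    all positive pairs keep only their self-connection (D~_ii = 1).
    """
    node_ids = list(node_ids)
    index = {pid: i for i, pid in enumerate(node_ids)}
    n = len(node_ids)
    A = np.zeros((n, n), dtype=np.float64)
    edges: set[frozenset] = set()
    for pair in train_pairs:
        for pid in (pair.id_a, pair.id_b):
            if pid not in index:
                raise IntegrityError(
                    f"pair references protein {pid!r} outside the node set"
                )
        if pair.label != 1:
            continue
        i, j = index[pair.id_a], index[pair.id_b]
        if i == j:
            continue  # self-interaction adds nothing beyond the self-loop
        A[i, j] = A[j, i] = 1.0
        edges.add(pair.key)
    A_tilde = A + np.eye(n)
    D_tilde = np.diag(A_tilde.sum(axis=1))
    return PPIGraph(node_ids=node_ids, edges=edges,
                    A=A, A_tilde=A_tilde, D_tilde=D_tilde)


def normalized_adjacency(graph: PPIGraph) -> np.ndarray:
    """Row-stochastic normalized adjacency ``D~^-1 A~``.

    Entry (i, j) is ``A~_ij / D~_ii``; every row sums to exactly 1 because
    the self-connection guarantees ``D~_ii >= 1``.
    """
    deg = graph.degrees
    return graph.A_tilde / deg[:, None]


@dataclass
class GCNLayer:
    """One graph-convolution layer: trainable ``W0`` plus an activation."""

    W0: np.ndarray
    activation: Callable[[np.ndarray], np.ndarray] = relu

    @property
    def f(self) -> int:
        return self.W0.shape[1]


def init_gcn_layer(n_nodes: int, f: int, rng: np.random.Generator,
                   activation: Callable[[np.ndarray], np.ndarray] = relu,
                   ) -> GCNLayer:
    """Initialize W0 (N x f) uniformly scaled by fan-in.

    The GCN input X0 is the identity (one-hot node features), so each
    node activates exactly one W0 row: the effective fan-in is 1 and the
    bound is 1.  Scaling by 1/sqrt(N) instead would shrink the position
    block by an order of magnitude relative to the {0,1} sequence
    features it is concatenated with, starving that channel of gradient.
    """
    if f < 1:
        raise ValueError(f"embedding width f must be >= 1, got {f}")
    W0 = rng.uniform(-1.0, 1.0, size=(n_nodes, f))
    return GCNLayer(W0=W0, activation=activation)


def gcn_embed(graph: PPIGraph, layer: GCNLayer) -> np.ndarray:
    """Compute the N x f position embedding ``X1 = sigma(D~^-1 A~ W0)``.

    ``X0`` is the identity (one-hot protein features) and is simplified
    away analytically.
    """
    if layer.W0.shape[0] != graph.n_nodes:
        raise ValueError(
            f"W0 has {layer.W0.shape[0]} rows but the graph has "
            f"{graph.n_nodes} nodes"
        )
    return layer.activation(normalized_adjacency(graph) @ layer.W0)


def export_edge_list(graph: PPIGraph, path) -> None:
    """Write the training graph's positive edges as 2-column text."""
    with open(path, "w") as fh:
        for edge in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{edge[0]}\t{edge[1]}\n")
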