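import numpy as np
import pytest

from gcnppi.data_io import Dataset, InteractionPair, SequenceRecord


@pytest.fixture
def toy_records():
    return [
        SequenceRecord("P1", "MKVLA"),
        SequenceRecord("P2", "ACDEF"),
        SequenceRecord("P3", "GHIKL"),
        SequenceRecord("P4", "MNPQR"),
    ]


@pytest.fixture
def star_pairs():
    """The worked-example star: P1 interacts with P2, P3 and P4."""
    return [
        InteractionPair("P1", "P2", 1),
        InteractionPair("P1", "P3", 1),
        InteractionPair("P1", "P4", 1),
    ]


@pytest.fixture
def star_dataset(toy_records, star_pairs):
    return Dataset(records=toy_records, pairs=star_pairs, name="star")


def brute_force_gcn(A_tilde, D_tilde, X0, W0, activation=None):
    """Per-node neighborhood-aggregation oracle for one GCN layer.

    Implements h_i = sigma( sum_{j in closed N(i)} (1 / D~_ii) x_j W )
    node by node, keeping the explicit X0 @ W product rather than the
    analytic simplification used by the implementation.
    """
    n = A_tilde.shape[0]
    H = X0 @ W0
    out = np.zeros((n, W0.shape[1]))
    for i in range(n):
        acc = np.zeros(W0.shape[1])
        for j in range(n):
            if A_tilde[i, j]:
                acc += H[j] / D_tilde[i, i]
        out[i] = acc
    if activation is not None:
        out = activation(out)
    return out


def brute_force_pr(scores, labels):
    """Exhaustive-threshold PR oracle: one point per distinct score.

    Area is the rectangle sum with precision held constant between
    consecutive recall points, recall starting from 0.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    points = []
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        points.append((tp / (tp + fn), tp / (tp + fp)))
    area = 0.0
    prev_r = 0.0
    for r, p in points:
        area += (r - prev_r) * p
        prev_r = r
    return points, area
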