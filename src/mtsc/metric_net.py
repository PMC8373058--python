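"""Embedding network and N-pair metric-learning loss.

The embedding kernel f(.; theta) is a small fully connected network —
input layer sized to the gene union, one rectified hidden layer (default
500 units) and a linear 20-dimensional output. Same-type cells should end
up with large inner products, different-type cells with small ones; the
N-pair loss drives this by comparing, for each anchor cell, the positive
of its own type against the positives of every other type in the batch:

    L = (1/N) * sum_i log(1 + sum_{j != i} exp(f_i . f_j+  -  f_i . f_i+))

All arithmetic is float64 numpy; gradients are computed analytically,
which keeps training deterministic and makes finite-difference checking
straightforward.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import BatchConstructionError, DimensionError
from .io_preprocess import AnnotatedDataset

__all__ = [
    "EmbeddingNetwork",
    "NPairBatch",
    "init_network",
    "embed",
    "sample_npair_batch",
    "npair_loss",
    "npair_loss_and_grad",
    "multitask_loss_and_grad",
]


@dataclasses.dataclass
class EmbeddingNetwork:
    """Two affine maps with a rectifier in between; no output nonlinearity.

    Embeddings are deliberately not length-normalized: the loss operates
    on raw inner products.
    """

    W1: np.ndarray  # (input_dim, hidden_dim)
    b1: np.ndarray  # (hidden_dim,)
    W2: np.ndarray  # (hidden_dim, embed_dim)
    b2: np.ndarray  # (embed_dim,)
    activation: str = "relu"

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def embed_dim(self) -> int:
        return self.W2.shape[1]

    def parameters(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}


@dataclasses.dataclass
class NPairBatch:
    """N (anchor, positive) pairs drawn from N distinct cell types.

    Row i of ``anchors`` and of ``positives`` are two different cells of
    the same type; the implicit tuple S_i is {anchor_i} + all positives.
    """

    anchors: np.ndarray    # (N, input_dim)
    positives: np.ndarray  # (N, input_dim)
    labels: list[str]      # N distinct cell-type names

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise BatchConstructionError("an N-pair batch needs N >= 2 cell types")
        if len(set(self.labels)) != n:
            raise BatchConstructionError("anchor labels must be pairwise distinct")
        if self.anchors.shape != self.positives.shape or self.anchors.shape[0] != n:
            raise DimensionError("anchors/positives must both be (N, input_dim)")

    @property
    def n_classes(self) -> int:
        return len(self.labels)


def init_network(input_dim: int, hidden_dim: int = 500, embed_dim: int = 20,
                 seed: int = 0) -> EmbeddingNetwork:
    """Initialize weights and biases uniformly on +-1/sqrt(fan_in).

    Deterministic: the same seed always yields identical parameters.
    """
    if min(input_dim, hidden_dim, embed_dim) < 1:
        raise ValueError("all layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    s1 = 1.0 / np.sqrt(input_dim)
    s2 = 1.0 / np.sqrt(hidden_dim)
    return EmbeddingNetwork(
        W1=rng.uniform(-s1, s1, size=(input_dim, hidden_dim)),
        b1=rng.uniform(-s1, s1, size=hidden_dim),
        W2=rng.uniform(-s2, s2, size=(hidden_dim, embed_dim)),
        b2=rng.uniform(-s2, s2, size=embed_dim),
    )


def _forward(net: EmbeddingNetwork, X: np.ndarray):
    Z1 = X @ net.W1 + net.b1
    H = np.maximum(Z1, 0.0)
    return Z1, H, H @ net.W2 + net.b2


def embed(net: EmbeddingNetwork, cells: np.ndarray) -> np.ndarray:
    """Map cells (rows, in gene-union space) to embedding vectors."""
    cells = np.atleast_2d(np.asarray(cells, dtype=np.float64))
    if cells.shape[1] != net.input_dim:
        raise DimensionError(
            f"expected {net.input_dim} input features, got {cells.shape[1]}"
        )
    return _forward(net, cells)[2]


def sample_npair_batch(ds: AnnotatedDataset,
                       rng: np.random.Generator) -> NPairBatch:
    """Draw one (anchor, positive) pair per cell type, without replacement.

    N equals the number of cell types present in the dataset; every type
    must have at least two cells.
    """
    if ds.labels is None:
        raise BatchConstructionError(f"{ds.name}: batch sampling needs labels")
    by_type: dict[str, list[int]] = {}
    for i, lab in enumerate(ds.labels):
        by_type.setdefault(lab, []).append(i)
    return _sample_from_index(ds.name, ds.matrix, by_type, rng)


def _sample_from_index(name: str, matrix: np.ndarray,
                       by_type: dict[str, list[int]],
                       rng: np.random.Generator) -> NPairBatch:
    labels = sorted(by_type)
    if len(labels) < 2:
        raise BatchConstructionError(f"{name}: need >= 2 cell types, got {len(labels)}")
    anchors, positives = [], []
    for lab in labels:
        idx = by_type[lab]
        if len(idx) < 2:
            raise BatchConstructionError(
                f"{name}: cell type {lab!r} has {len(idx)} cells (< 2)"
            )
        a, p = rng.choice(len(idx), size=2, replace=False)
        anchors.append(matrix[idx[a]])
        positives.append(matrix[idx[p]])
    return NPairBatch(
        anchors=np.asarray(anchors), positives=np.asarray(positives), labels=labels
    )


def _loss_terms(F: np.ndarray, Fp: np.ndarray):
    """Per-anchor log-sum terms and softmax weights, computed stably.

    Returns (loss, P) where P[i, j] = exp(d_ij - s_i) for j != i (0 on the
    diagonal), d_ij = f_i.f_j+ - f_i.f_i+ and s_i the log of the full sum
    1 + sum_j exp(d_ij); a max-shift keeps the exponentials bounded.
    """
    n = F.shape[0]
    sims = F @ Fp.T                        # sims[i, j] = f_i . f_j+
    d = sims - np.diag(sims)[:, None]      # d[i, i] = 0
    off = ~np.eye(n, dtype=bool)
    # logsumexp over {0} U {d_ij : j != i}; note exp(d_ii) = 1 stands in
    # for the constant 1 inside log(1 + ...).
    m = np.maximum(d.max(axis=1, where=off, initial=-np.inf), 0.0)
    z = np.exp(-m) + np.where(off, np.exp(d - m[:, None]), 0.0).sum(axis=1)
    s = m + np.log(z)                      # s_i = log(1 + sum_{j!=i} exp(d_ij))
    loss = float(s.mean())
    P = np.where(off, np.exp(d - s[:, None]), 0.0)
    return loss, P


def npair_loss(net: EmbeddingNetwork, batch: NPairBatch) -> float:
    """Evaluate the N-pair loss for one batch; always >= 0."""
    F = embed(net, batch.anchors)
    Fp = embed(net, batch.positives)
    return _loss_terms(F, Fp)[0]


def multitask_loss_and_grad(net: EmbeddingNetwork, batches: list[NPairBatch]):
    """Summed loss over task batches plus its analytic parameter gradient.

    All batches flow through the one shared network in a single stacked
    forward/backward pass. Gradient of one batch's loss in its
    embeddings, with weights P from ``_loss_terms``:
        dL/dF_i  = (1/N) sum_{j!=i} P_ij (Fp_j - Fp_i)
        dL/dFp_k = (1/N) [ sum_{i!=k} P_ik F_i - (sum_j P_kj) F_k ]
    which is then backpropagated through the two affine layers.
    """
    if not batches:
        raise ValueError("need at least one batch")
    X = np.vstack([np.vstack([b.anchors, b.positives]) for b in batches])
    Z1, H, F_all = _forward(net, X)

    total_loss = 0.0
    G = np.empty_like(F_all)
    offset = 0
    for b in batches:
        n = b.n_classes
        F, Fp = F_all[offset: offset + n], F_all[offset + n: offset + 2 * n]
        loss, P = _loss_terms(F, Fp)
        total_loss += loss
        row = P.sum(axis=1)                              # sum_j P_ij
        G[offset: offset + n] = (P @ Fp - row[:, None] * Fp) / n
        G[offset + n: offset + 2 * n] = (P.T @ F - row[:, None] * F) / n
        offset += 2 * n

    grads = {"W2": H.T @ G, "b2": G.sum(axis=0)}
    dH = G @ net.W2.T
    dZ1 = dH * (Z1 > 0.0)
    grads["W1"] = X.T @ dZ1
    grads["b1"] = dZ1.sum(axis=0)
    return total_loss, grads


def npair_loss_and_grad(net: EmbeddingNetwork, batch: NPairBatch):
    """Loss and analytic parameter gradient for a single batch."""
    return multitask_loss_and_grad(net, [batch])
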