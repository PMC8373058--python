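"""Multitask training of the parameter-shared embedding network.

Each reference dataset is one learning task. Every iteration draws one
N-pair batch per task, evaluates the N-pair loss of each, and updates a
single fully shared set of network parameters with the summed loss —
labels never leave their own task, so references with different cell-type
vocabularies train together safely. The optimizer is adaptive-moment
gradient descent (Adam, default moment constants) with a decoupled L2
weight-decay penalty.

One epoch is defined as ceil(max_task cells / (2 N_task)) iterations, so
the largest task's cells are each expected to be seen about once per
epoch; batches are resampled fresh every iteration.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .assign import TransformedReference, compute_centroids
from .errors import ModelLoadError, UntrainableTaskError
from .io_preprocess import AnnotatedDataset, GeneUnion
from .metric_net import (
    EmbeddingNetwork,
    _sample_from_index,
    init_network,
    multitask_loss_and_grad,
)

__all__ = ["TrainConfig", "TrainedModel", "train", "save_model", "load_model"]

_FORMAT_VERSION = "mtsc-model-1"
_ADAM_BETA1, _ADAM_BETA2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults: lr 5e-4, 300 epochs, L2 0.05)."""

    learning_rate: float = 0.0005
    epochs: int = 300
    l2_rate: float = 0.05
    batches_per_epoch: int | None = None  # None: sized to the largest task
    seed: int = 0
    hidden_dim: int = 500
    embed_dim: int = 20

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l2_rate < 0:
            raise ValueError("l2_rate must be non-negative")


@dataclasses.dataclass
class TrainedModel:
    """A trained network plus everything needed to assign query cells."""

    network: EmbeddingNetwork
    gene_union: GeneUnion
    references: list[TransformedReference]
    config: TrainConfig
    loss_history: list[float]

    @property
    def m(self) -> int:
        """Number of training tasks (reference datasets)."""
        return len(self.references)


def _type_index(ds: AnnotatedDataset) -> dict[str, list[int]]:
    by_type: dict[str, list[int]] = {}
    for i, lab in enumerate(ds.labels):
        by_type.setdefault(lab, []).append(i)
    return by_type


def train(refs: Sequence[AnnotatedDataset], cfg: TrainConfig = TrainConfig()) -> TrainedModel:
    """Train the shared network on all reference tasks simultaneously.

    All references must be normalized and aligned to one gene union
    (identical ``gene_ids``). Deterministic given ``cfg.seed``.
    """
    if not refs:
        raise ValueError("need at least one reference dataset")
    genes = refs[0].gene_ids
    for ds in refs:
        if not ds.normalized:
            raise ValueError(f"{ds.name}: reference not normalized")
        if ds.gene_ids != genes:
            raise ValueError(f"{ds.name}: references not aligned to one gene union")
        if ds.labels is None:
            raise UntrainableTaskError(f"{ds.name}: reference has no labels")
    indices = [_type_index(ds) for ds in refs]
    for ds, idx in zip(refs, indices):
        if len(idx) < 2:
            raise UntrainableTaskError(
                f"{ds.name}: only {len(idx)} cell type(s); need >= 2 to train"
            )
        thin = [t for t, rows in idx.items() if len(rows) < 2]
        if thin:
            raise UntrainableTaskError(
                f"{ds.name}: cell type(s) with < 2 cells: {', '.join(sorted(thin))}"
            )

    if cfg.batches_per_epoch is None:
        batches_per_epoch = max(
            math.ceil(ds.n_cells / (2 * len(idx)))
            for ds, idx in zip(refs, indices)
        )
    else:
        batches_per_epoch = cfg.batches_per_epoch

    rng = np.random.default_rng(cfg.seed)
    net = init_network(len(genes), cfg.hidden_dim, cfg.embed_dim,
                       seed=int(rng.integers(2 ** 31)))
    params = net.parameters()
    mom1 = {k: np.zeros_like(v) for k, v in params.items()}
    mom2 = {k: np.zeros_like(v) for k, v in params.items()}
    scratch = {k: np.empty_like(v) for k, v in params.items()}
    t = 0

    loss_history: list[float] = []
    for _ in range(cfg.epochs):
        epoch_losses = []
        for _ in range(batches_per_epoch):
            batches = [
                _sample_from_index(ds.name, ds.matrix, idx, rng)
                for ds, idx in zip(refs, indices)
            ]
            total_loss, total_grads = multitask_loss_and_grad(net, batches)
            t += 1
            bc1 = 1.0 - _ADAM_BETA1 ** t
            bc2 = 1.0 - _ADAM_BETA2 ** t
            # Adam with decoupled weight decay; in-place updates, one
            # scratch buffer per parameter (``g`` may be destroyed).
            for k, p in params.items():
                g, s = total_grads[k], scratch[k]
                np.multiply(g, g, out=s)
                mom2[k] *= _ADAM_BETA2
                s *= 1.0 - _ADAM_BETA2
                mom2[k] += s
                mom1[k] *= _ADAM_BETA1
                g *= 1.0 - _ADAM_BETA1
                mom1[k] += g
                np.sqrt(mom2[k], out=s)
                s /= np.sqrt(bc2)
                s += _ADAM_EPS
                np.divide(mom1[k], s, out=s)
                s *= cfg.learning_rate / bc1
                if cfg.l2_rate:
                    p *= 1.0 - cfg.learning_rate * cfg.l2_rate
                p -= s
            epoch_losses.append(total_loss)
        loss_history.append(float(np.mean(epoch_losses)))

    return TrainedModel(
        network=net,
        gene_union=GeneUnion(genes=tuple(genes)),
        references=[compute_centroids(net, ds) for ds in refs],
        config=cfg,
        loss_history=loss_history,
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write the model as a single versioned archive of named arrays."""
    arrays: dict[str, np.ndarray] = {
        "format_version": np.array(_FORMAT_VERSION),
        "W1": model.network.W1,
        "b1": model.network.b1,
        "W2": model.network.W2,
        "b2": model.network.b2,
        "gene_union": np.array(model.gene_union.genes),
        "config": np.array(json.dumps(dataclasses.asdict(model.config))),
        "loss_history": np.array(model.loss_history),
        "ref_names": np.array([r.name for r in model.references]),
    }
    for i, ref in enumerate(model.references):
        arrays[f"ref{i}_cell_types"] = np.array(ref.cell_types)
        arrays[f"ref{i}_centroids"] = ref.centroids
    # Write through a buffer so a failed write cannot leave a torso that
    # np.load would partially accept.
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_model(path: str | Path) -> TrainedModel:
    """Load a model archive written by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise ModelLoadError(f"{path}: no such file")
    try:
        with np.load(path, allow_pickle=False) as data:
            if "format_version" not in data:
                raise ModelLoadError(f"{path}: not an mtsc model archive")
            version = str(data["format_version"])
            if version != _FORMAT_VERSION:
                raise ModelLoadError(
                    f"{path}: unsupported model format {version!r} "
                    f"(expected {_FORMAT_VERSION!r})"
                )
            cfg = TrainConfig(**json.loads(str(data["config"])))
            net = EmbeddingNetwork(
                W1=data["W1"], b1=data["b1"], W2=data["W2"], b2=data["b2"]
            )
            refs = [
                TransformedReference(
                    name=str(name),
                    cell_types=[str(t) for t in data[f"ref{i}_cell_types"]],
                    centroids=data[f"ref{i}_centroids"],
                )
                for i, name in enumerate(data["ref_names"])
            ]
            return TrainedModel(
                network=net,
                gene_union=GeneUnion(genes=tuple(str(g) for g in data["gene_union"])),
                config=cfg,
                references=refs,
                loss_history=[float(x) for x in data["loss_history"]],
            )
    except ModelLoadError:
        raise
    except Exception as exc:  # truncated/corrupt zip, missing keys, ...
        raise ModelLoadError(f"{path}: cannot load model: {exc}") from exc
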