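"""Query-cell assignment against embedded reference centroids.

After training, each reference is summarized by one centroid per cell
type: the mean embedding of that type's cells. A query cell is embedded
once, its Pearson correlation with every centroid of every reference in
the decision set is computed, and the label of the best-correlated
centroid wins — decision-level integration across references. Every
query cell receives a label; there is deliberately no "unassigned"
outcome or rejection threshold.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_preprocess import AnnotatedDataset
from .metric_net import EmbeddingNetwork, embed

if TYPE_CHECKING:  # avoid a circular import at run time
    from .multitask_train import TrainedModel

logger = logging.getLogger(__name__)

__all__ = [
    "TransformedReference",
    "AssignmentResult",
    "compute_centroids",
    "pearson_similarity",
    "assign_cells",
]


@dataclasses.dataclass
class TransformedReference:
    """Per-cell-type centroid embeddings of one reference dataset."""

    name: str
    cell_types: list[str]
    centroids: np.ndarray  # (K, embed_dim)

    def __post_init__(self) -> None:
        if len(self.cell_types) != self.centroids.shape[0]:
            raise ValueError(f"{self.name}: one centroid row per cell type required")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError(f"{self.name}: duplicate cell-type labels")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError(f"{self.name}: non-finite centroid")


@dataclasses.dataclass
class AssignmentResult:
    """Predicted label, winning similarity and source reference per cell."""

    cell_ids: list[str]
    predicted_labels: list[str]
    best_similarity: np.ndarray
    source_reference: list[str]
    similarity_table: pd.DataFrame | None = None  # cells x (reference, cell_type)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "predicted_type": self.predicted_labels,
                "best_similarity": self.best_similarity,
                "source_reference": self.source_reference,
            }
        )

    def write_tsv(self, path: str | Path,
                  similarity_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if similarity_path is not None and self.similarity_table is not None:
            long = self.similarity_table.stack([0, 1], future_stack=True)
            long.name = "similarity"
            long.rename_axis(["cell_id", "reference", "cell_type"]).reset_index().to_csv(
                similarity_path, sep="\t", index=False
            )


def compute_centroids(net: EmbeddingNetwork, ref: AnnotatedDataset) -> TransformedReference:
    """Embed a labeled reference and average embeddings within each type."""
    if ref.labels is None:
        raise ValueError(f"{ref.name}: centroids need labels")
    emb = embed(net, ref.matrix)
    types = sorted(set(ref.labels))
    labels = np.asarray(ref.labels)
    centroids = np.vstack([emb[labels == t].mean(axis=0) for t in types])
    return TransformedReference(name=ref.name, cell_types=types, centroids=centroids)


def pearson_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two embedding vectors.

    A constant vector has no defined correlation; it is mapped to -inf so
    that such a centroid (or query embedding) can never win an argmax.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    du, dv = u - u.mean(), v - v.mean()
    su, sv = np.sqrt((du ** 2).sum()), np.sqrt((dv ** 2).sum())
    if su == 0.0 or sv == 0.0:
        return -np.inf
    return float(np.clip((du @ dv) / (su * sv), -1.0, 1.0))


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale rows so that z_u @ z_v.T is the Pearson r matrix."""
    d = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((d ** 2).sum(axis=1, keepdims=True))
    constant = norm[:, 0] == 0.0
    with np.errstate(invalid="ignore"):
        z = np.where(constant[:, None], 0.0, d / np.where(constant[:, None], 1.0, norm))
    return z, constant


def assign_cells(model: "TrainedModel", query: AnnotatedDataset,
                 decision_refs: Sequence[str] | None = None,
                 keep_similarity_table: bool = False) -> AssignmentResult:
    """Assign every query cell the best-correlated centroid's cell type.

    ``decision_refs`` restricts the decision set to a subset of the
    trained references (all by default) — used e.g. for cross-species
    assignment, where auxiliary references help training but must not
    vote. Ties in similarity are broken deterministically by (reference
    name, cell type) lexicographic order.
    """
    if not query.normalized:
        raise ValueError(f"{query.name}: query must be normalized before assignment")
    known = {r.name for r in model.references}
    if decision_refs is None:
        refs = list(model.references)
    else:
        unknown = [n for n in decision_refs if n not in known]
        if unknown:
            raise ConfigurationError(
                f"unknown reference name(s) in decision set: {', '.join(unknown)}"
            )
        refs = [r for r in model.references if r.name in set(decision_refs)]
    if not refs:
        raise ConfigurationError("the decision set is empty")

    # Columns sorted by (reference, cell type) so np.argmax's first-max
    # rule realizes the documented tie-break.
    columns = sorted(
        (ref.name, t, ref.centroids[k])
        for ref in refs
        for k, t in enumerate(ref.cell_types)
    )
    cent = np.vstack([c for _, _, c in columns])
    zc, const_c = _standardize_rows(cent)
    if const_c.any():
        bad = [f"{r}/{t}" for (r, t, _), c in zip(columns, const_c) if c]
        logger.warning(
            "constant centroid embedding(s) excluded from the decision: %s",
            ", ".join(bad),
        )

    emb = embed(model.network, query.matrix)
    zq, const_q = _standardize_rows(emb)
    if const_q.any():
        logger.warning(
            "%d query cell(s) have constant embeddings; their similarities "
            "are undefined and set to -inf",
            int(const_q.sum()),
        )
    sims = zq @ zc.T
    sims[const_q, :] = -np.inf
    sims[:, const_c] = -np.inf

    best = sims.argmax(axis=1)
    result = AssignmentResult(
        cell_ids=list(query.cell_ids),
        predicted_labels=[columns[j][1] for j in best],
        best_similarity=sims[np.arange(len(best)), best],
        source_reference=[columns[j][0] for j in best],
    )
    if keep_similarity_table:
        result.similarity_table = pd.DataFrame(
            sims,
            index=pd.Index(query.cell_ids, name="cell_id"),
            columns=pd.MultiIndex.from_tuples(
                [(r, t) for r, t, _ in columns], names=["reference", "cell_type"]
            ),
        )
    return result
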