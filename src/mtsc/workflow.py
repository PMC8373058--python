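"""End-to-end helpers: preprocess -> train -> assign.

Thin glue used by the command-line interface and by the experiment
drivers, so that every entry point runs the identical pipeline.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import io_preprocess as iop
from .assign import AssignmentResult, assign_cells
from .multitask_train import TrainConfig, TrainedModel, train

__all__ = ["preprocess_references", "train_references", "prepare_query", "assign_query"]


def preprocess_references(
    refs: Sequence[iop.AnnotatedDataset],
    qc: iop.QCThresholds | None = iop.QCThresholds(),
    min_cells_per_type: int = 10,
    scale: float = 10_000.0,
) -> list[iop.AnnotatedDataset]:
    """QC (unless ``qc`` is None) -> rare-type filter -> normalize -> align.

    Returns the references in the shared gene-union feature space.
    """
    out = []
    for ds in refs:
        if qc is not None:
            ds = iop.qc_filter(ds, qc)
        ds = iop.filter_rare_types(ds, min_cells=min_cells_per_type)
        out.append(iop.normalize(ds, scale=scale))
    union = iop.build_gene_union(out)
    return [iop.align_to_union(ds, union) for ds in out]


def train_references(
    refs: Sequence[iop.AnnotatedDataset],
    cfg: TrainConfig = TrainConfig(),
    qc: iop.QCThresholds | None = iop.QCThresholds(),
    min_cells_per_type: int = 10,
) -> TrainedModel:
    """Full training pipeline from raw labeled count matrices."""
    return train(preprocess_references(refs, qc=qc, min_cells_per_type=min_cells_per_type), cfg)


def prepare_query(
    query: iop.AnnotatedDataset,
    model: TrainedModel,
    qc: iop.QCThresholds | None = None,
    scale: float = 10_000.0,
) -> iop.AnnotatedDataset:
    """Optionally QC, then normalize and align a raw query to the model.

    Query quality control is opt-in; normalization and gene-union
    alignment always run. Query genes outside the training union are
    dropped, union genes absent from the query are zero-filled.
    """
    if qc is not None:
        query = iop.qc_filter(query, qc)
    query = iop.normalize(query, scale=scale)
    aligned = iop.align_to_union(query, model.gene_union)
    if not np.any(aligned.matrix):
        import logging

        logging.getLogger(__name__).warning(
            "%s: no overlap between query genes and the training gene union; "
            "all query features are zero",
            query.name,
        )
    return aligned


def assign_query(
    model: TrainedModel,
    query: iop.AnnotatedDataset,
    qc: iop.QCThresholds | None = None,
    decision_refs: Sequence[str] | None = None,
    keep_similarity_table: bool = False,
) -> AssignmentResult:
    """Preprocess a raw query and assign cell types."""
    prepared = prepare_query(query, model, qc=qc)
    return assign_cells(
        model, prepared, decision_refs=decision_refs,
        keep_similarity_table=keep_similarity_table,
    )
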