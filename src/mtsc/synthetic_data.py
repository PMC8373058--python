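"""Synthetic multi-batch scRNA-seq counts and desk-scale experiment drivers.

The generator emulates the structure the assignment method is built for:
several batches of the same tissue share one biology (per-type mean
expression profiles with marker genes) but differ by batch-specific
multiplicative per-gene distortions, on top of overdispersed (gamma-mixed
Poisson, i.e. negative-binomial-like) counting noise. It is NOT a
calibrated scRNA-seq simulator — no dropout/expression coupling, no
platform-specific library-size model — but it produces data on which
cell-type signal and batch effects can be dialed independently, which is
what the training and assignment code needs to be testable offline.

Also provided are drivers for two protocols: performance as a function of
the number of reference batches, and cross-species-style assignment where
auxiliary batches join training but are excluded from the decision set.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assign import assign_cells
from .evaluate import macro_f1
from .io_preprocess import AnnotatedDataset, write_dataset
from .multitask_train import TrainConfig, TrainedModel, train
from .workflow import preprocess_references, prepare_query

__all__ = [
    "SimConfig",
    "confusable_config",
    "simulate",
    "expected_profiles",
    "write_batches",
    "leave_one_out_experiment",
    "multitask_benefit_experiment",
    "scaling_experiment",
    "cross_species_experiment",
]


def _default_cell_types() -> dict[str, int]:
    return {f"type_{i}": 60 for i in range(4)}


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``cell_types`` maps type name -> cells per batch. ``marker_log_fold``
    is the natural-log fold change of a type's marker genes over baseline;
    ``batch_severity`` is the standard deviation of the per-batch, per-gene
    log-normal distortion factors (0 means all batches share one
    distribution). ``dispersion`` is the negative-binomial overdispersion
    (variance = mu + dispersion * mu^2). Types listed in
    ``confusable_pairs`` share ``confusable_shared_fraction`` of their
    marker genes, leaving only a small private marker set to tell them
    apart — the hard case that benefits from multiple references;
    ``confusable_private_fold_scale`` scales the log fold change of those
    private markers (1 keeps them as strong as the shared ones).
    ``mean_depth`` is the expected library size per cell (counts).
    """

    n_genes: int = 1000
    cell_types: dict[str, int] = dataclasses.field(default_factory=_default_cell_types)
    n_batches: int = 4
    marker_genes_per_type: int = 25
    marker_log_fold: float = 2.0
    batch_severity: float = 0.5
    dispersion: float = 0.3
    confusable_pairs: tuple[tuple[str, str], ...] | None = None
    confusable_shared_fraction: float = 0.8
    confusable_private_fold_scale: float = 1.0
    mean_depth: float = 3000.0
    libsize_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_batches < 1:
            raise ValueError("n_genes and n_batches must be >= 1")
        if any(c < 0 for c in self.cell_types.values()):
            raise ValueError("cell counts must be non-negative")
        if self.batch_severity < 0:
            raise ValueError("batch_severity must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.confusable_pairs:
            names = set(self.cell_types)
            for a, b in self.confusable_pairs:
                if a not in names or b not in names:
                    raise ValueError(f"confusable pair ({a}, {b}) names unknown types")
        needed = len(self.cell_types) * self.marker_genes_per_type
        if needed > self.n_genes:
            raise ValueError("not enough genes for the requested marker sets")


def confusable_config(seed: int = 0, n_batches: int = 4) -> SimConfig:
    """A harder design: two types share 80% of their markers.

    The five private marker genes per confusable type carry a weaker fold
    change than the shared ones, and the batch distortion is stronger, so
    a single reference batch rarely suffices to separate the pair while
    several references jointly do.
    """
    return SimConfig(
        cell_types={f"type_{i}": 60 for i in range(4)},
        n_batches=n_batches,
        confusable_pairs=(("type_0", "type_1"),),
        confusable_shared_fraction=0.8,
        confusable_private_fold_scale=0.5,
        batch_severity=1.0,
        seed=seed,
    )


def _marker_sets(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Assign marker gene indices per type; confusable pairs overlap.

    Returns (markers, private) where ``private`` holds, for each member of
    a confusable pair, the small marker subset not shared with its partner.
    """
    perm = rng.permutation(cfg.n_genes)
    k = cfg.marker_genes_per_type
    markers: dict[str, np.ndarray] = {}
    private: dict[str, np.ndarray] = {}
    pos = 0
    for name in cfg.cell_types:
        markers[name] = perm[pos: pos + k].copy()
        pos += k
    if cfg.confusable_pairs:
        s = int(round(cfg.confusable_shared_fraction * k))
        for a, b in cfg.confusable_pairs:
            markers[b][:s] = markers[a][:s]
            private[a] = markers[a][s:].copy()
            private[b] = markers[b][s:].copy()
    return markers, private


def _biology(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Per-type relative expression profiles, shared by every batch."""
    rng = np.random.default_rng([cfg.seed, 0])
    baseline = rng.gamma(shape=2.0, scale=1.0, size=cfg.n_genes) + 1e-3
    markers, private = _marker_sets(cfg, rng)
    profiles = {}
    for name in cfg.cell_types:
        fold = np.ones(cfg.n_genes)
        fold[markers[name]] = math.exp(cfg.marker_log_fold)
        if name in private:
            fold[private[name]] = math.exp(
                cfg.marker_log_fold * cfg.confusable_private_fold_scale
            )
        prof = baseline * fold
        profiles[name] = prof / prof.sum()
    return profiles


def expected_profiles(cfg: SimConfig) -> dict[str, dict[str, np.ndarray]]:
    """Exact per-batch, per-type relative mean expression (sums to 1).

    These are the distribution means the counts of :func:`simulate` are
    drawn around (up to library size), useful for checking batch-effect
    and marker structure without sampling noise.
    """
    profiles = _biology(cfg)
    out: dict[str, dict[str, np.ndarray]] = {}
    for b in range(cfg.n_batches):
        rng = np.random.default_rng([cfg.seed, b + 1])
        factors = np.exp(rng.normal(0.0, cfg.batch_severity, size=cfg.n_genes))
        batch = {}
        for name, prof in profiles.items():
            mean = prof * factors
            batch[name] = mean / mean.sum()
        out[f"batch{b}"] = batch
    return out


def simulate(cfg: SimConfig) -> list[AnnotatedDataset]:
    """Generate one labeled raw-count dataset per batch.

    Biology (baseline expression, marker assignment, per-type profiles)
    is drawn once and shared by all batches; each batch then gets its own
    log-normal per-gene distortion of scale ``batch_severity``. Counts are
    gamma-mixed Poisson around the distorted per-type means, scaled to a
    log-normal library size. Bitwise reproducible from ``cfg.seed``;
    biology and each batch use independent seeded substreams.
    """
    profiles = _biology(cfg)
    types = list(cfg.cell_types)
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    datasets = []
    for b in range(cfg.n_batches):
        rng = np.random.default_rng([cfg.seed, b + 1])
        factors = np.exp(rng.normal(0.0, cfg.batch_severity, size=cfg.n_genes))
        rows, labels, cell_ids = [], [], []
        for name in types:
            n = cfg.cell_types[name]
            mean = profiles[name] * factors
            mean = mean / mean.sum()
            libsizes = cfg.mean_depth * np.exp(
                rng.normal(-cfg.libsize_sigma ** 2 / 2, cfg.libsize_sigma, size=n)
            )
            mu = libsizes[:, None] * mean[None, :]
            lam = mu * rng.gamma(
                shape=1.0 / cfg.dispersion, scale=cfg.dispersion, size=mu.shape
            )
            rows.append(rng.poisson(lam))
            labels.extend([name] * n)
            cell_ids.extend(f"batch{b}_{name}_c{i:03d}" for i in range(n))
        datasets.append(
            AnnotatedDataset(
                name=f"batch{b}",
                matrix=np.vstack(rows).astype(np.float64),
                cell_ids=cell_ids,
                gene_ids=list(gene_ids),
                labels=labels,
                normalized=False,
            )
        )
    return datasets


def write_batches(datasets: Sequence[AnnotatedDataset], outdir: str | Path) -> None:
    """Write each batch as <name>.tsv plus <name>.labels.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        write_dataset(ds, outdir / f"{ds.name}.tsv", outdir / f"{ds.name}.labels.tsv")


def _fit_and_score(
    refs: Sequence[AnnotatedDataset],
    query: AnnotatedDataset,
    train_cfg: TrainConfig,
    decision_refs: Sequence[str] | None = None,
    restrict_types: Sequence[str] | None = None,
) -> tuple[float, TrainedModel]:
    """Preprocess, train, assign the held-out batch, and score macro-F1.

    Synthetic cells are generated healthy, so the drivers skip cell QC and
    run rare-type filtering, normalization and union alignment only.
    ``restrict_types`` limits scoring to query cells of the given true
    types (used for the confusable-pair comparisons).
    """
    model = train(preprocess_references(refs, qc=None), train_cfg)
    prepared = prepare_query(query, model)
    result = assign_cells(model, prepared, decision_refs=decision_refs)
    truth = list(query.labels)
    pred = list(result.predicted_labels)
    if restrict_types is not None:
        wanted = set(restrict_types)
        keep = [i for i, t in enumerate(truth) if t in wanted]
        truth = [truth[i] for i in keep]
        pred = [pred[i] for i in keep]
    score, _ = macro_f1(truth, pred)
    return score, model


def leave_one_out_experiment(
    datasets: Sequence[AnnotatedDataset],
    query_index: int,
    train_cfg: TrainConfig,
) -> float:
    """Hold one batch out as query, train on the rest, return macro-F1."""
    query = datasets[query_index]
    refs = [d for i, d in enumerate(datasets) if i != query_index]
    score, _ = _fit_and_score(refs, query, train_cfg)
    return score


def multitask_benefit_experiment(
    cfg: SimConfig,
    train_cfg: TrainConfig,
    query_index: int = 0,
) -> dict[str, float]:
    """Multitask vs each single-reference run, scored on confusable types.

    Returns ``{"multitask": f1, "single:<batch>": f1, ...}`` where each
    score is the held-out macro-F1 restricted to the cells of the
    confusable cell types.
    """
    if not cfg.confusable_pairs:
        raise ValueError("config has no confusable pairs to evaluate")
    focus = sorted({t for pair in cfg.confusable_pairs for t in pair})
    datasets = simulate(cfg)
    query = datasets[query_index]
    refs = [d for i, d in enumerate(datasets) if i != query_index]
    out: dict[str, float] = {}
    out["multitask"], _ = _fit_and_score(refs, query, train_cfg, restrict_types=focus)
    for ref in refs:
        score, _ = _fit_and_score([ref], query, train_cfg, restrict_types=focus)
        out[f"single:{ref.name}"] = score
    return out


def scaling_experiment(
    cfg: SimConfig,
    max_refs: int,
    repeats: int,
    train_cfg: TrainConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Macro-F1 as the number of reference batches grows.

    For each r in 2..max_refs and each repeat: pick a random query batch,
    pick r of the remaining batches as references, train and score.
    Returns a table with columns (n_refs, repeat, query_batch, train_seed,
    macro_f1).
    """
    if cfg.n_batches < max_refs + 1:
        raise ValueError("need n_batches >= max_refs + 1")
    if train_cfg is None:
        train_cfg = TrainConfig(epochs=50)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    datasets = simulate(cfg)
    rows = []
    for r in range(2, max_refs + 1):
        for rep in range(repeats):
            qi = int(rng.integers(cfg.n_batches))
            others = [i for i in range(cfg.n_batches) if i != qi]
            chosen = rng.choice(len(others), size=r, replace=False)
            refs = [datasets[others[i]] for i in chosen]
            train_seed = int(rng.integers(2 ** 31))
            run_cfg = dataclasses.replace(train_cfg, seed=train_seed)
            score, _ = _fit_and_score(refs, datasets[qi], run_cfg)
            rows.append(
                {
                    "n_refs": r,
                    "repeat": rep,
                    "query_batch": datasets[qi].name,
                    "train_seed": train_seed,
                    "macro_f1": score,
                }
            )
    return pd.DataFrame(rows)


def _stratified_split(
    ds: AnnotatedDataset, fraction: float, rng: np.random.Generator
) -> tuple[AnnotatedDataset, AnnotatedDataset]:
    """Split one batch per cell type into (reference part, query part)."""
    labels = np.asarray(ds.labels)
    ref_idx: list[int] = []
    for t in sorted(set(ds.labels)):
        idx = np.flatnonzero(labels == t)
        n_ref = max(2, int(round(fraction * len(idx))))
        ref_idx.extend(rng.choice(idx, size=n_ref, replace=False))
    ref_mask = np.zeros(ds.n_cells, dtype=bool)
    ref_mask[ref_idx] = True
    ref = dataclasses.replace(ds.subset_cells(ref_mask), name=f"{ds.name}_ref")
    query = dataclasses.replace(ds.subset_cells(~ref_mask), name=f"{ds.name}_query")
    return ref, query


def cross_species_experiment(
    cfg: SimConfig,
    target_fraction: float,
    train_cfg: TrainConfig | None = None,
    min_cells_per_type: int | None = None,
) -> tuple[float, float]:
    """Auxiliary batches help training but are excluded from the decision.

    Batch 0 plays the data-poor target species: a ``target_fraction``
    stratified split of it is the only reference allowed in the decision
    set, the remainder is the query. The other batches stand in for a
    related species — useful during multitask training, untrustworthy for
    the final vote. Returns (multitask macro-F1, single-task macro-F1),
    both with the decision set restricted to the target reference.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie strictly between 0 and 1")
    if train_cfg is None:
        train_cfg = TrainConfig(epochs=50)
    datasets = simulate(cfg)
    rng = np.random.default_rng(train_cfg.seed)
    target_ref, query = _stratified_split(datasets[0], target_fraction, rng)
    aux = datasets[1:]
    if min_cells_per_type is None:
        min_cells_per_type = min(
            10, min(pd.Series(target_ref.labels).value_counts())
        )

    def run(refs: Sequence[AnnotatedDataset]) -> float:
        model = train(
            preprocess_references(refs, qc=None, min_cells_per_type=min_cells_per_type),
            train_cfg,
        )
        prepared = prepare_query(query, model)
        result = assign_cells(model, prepared, decision_refs=[target_ref.name])
        score, _ = macro_f1(list(query.labels), result.predicted_labels)
        return score

    return run([target_ref] + list(aux)), run([target_ref])
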