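"""Iterative backward elimination of genes driven by forest importance.

The driver starts from the full gene set, repeatedly fits a fresh balanced
forest, removes every gene whose OOB permutation importance is non-positive,
and records OOB and validation error along the way. Two refinements keep
the loop honest on real data:

* a *progress floor* — once every surviving gene has positive importance
  the plain rule would stall, so the lowest ``ceil(floor_fraction * d)``
  genes are dropped instead;
* *early stopping* — a stratified validation split is scored each
  iteration, and the loop stops once the validation error has not improved
  on its running minimum for ``patience`` consecutive iterations, guarding
  against selecting an over-fitted subset.

For very wide matrices an optional first pass partitions the genes into
random chunks, screens each chunk with its own forest, and keeps only genes
with positive importance in their chunk; the union of survivors seeds the
main loop. Chunking trades some cross-chunk correlation for speed in the
first iteration only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import forest as forest_mod
from .data_io import ExpressionDataset, RunConfig
from .forest import ImportanceVector
from .synthetic import stratified_split

__all__ = [
    "TraceRecord",
    "IterationTrace",
    "SelectionResult",
    "early_stop",
    "eliminate",
    "chunk_first_pass",
    "run_birf",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TraceRecord:
    """State of one elimination iteration."""

    iteration: int
    gene_ids: tuple[str, ...]
    n_genes: int
    oob_error: float
    validation_error: float | None
    importance: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class IterationTrace:
    """Ordered per-iteration records; gene sets are strictly nested."""

    records: tuple[TraceRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        prev: set[str] | None = None
        for rec in self.records:
            cur = set(rec.gene_ids)
            if prev is not None and not (cur < prev):
                raise ValueError("gene sets must strictly nest across iterations")
            prev = cur

    def oob_errors(self) -> list[float]:
        return [r.oob_error for r in self.records]

    def validation_errors(self) -> list[float | None]:
        return [r.validation_error for r in self.records]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selection run.

    ``selected_genes`` is the surviving set at the validation-error minimum
    (or at the smallest OOB error when no validation split is used),
    ordered by descending importance at that iteration. ``config`` is the
    resolved configuration including the seed, sufficient to reproduce the
    run exactly.
    """

    selected_genes: tuple[str, ...]
    stop_iteration: int
    stop_reason: str
    best_iteration: int
    trace: IterationTrace
    config: RunConfig


def early_stop(validation_errors, patience: int) -> tuple[bool, int]:
    """Running-minimum early-stopping rule.

    Returns ``(stop_now, best_iteration)`` where ``best_iteration`` is the
    1-based index of the running minimum (earliest on ties) and ``stop_now``
    is true once ``patience`` consecutive iterations have passed since the
    minimum without improving on it.
    """
    errors = list(validation_errors)
    if not errors:
        raise ValueError("at least one recorded error required")
    if patience < 1:
        raise ValueError("patience must be >= 1")
    best = 1 + int(np.argmin(errors))  # np.argmin takes the earliest tie
    stop = (len(errors) - best) >= patience
    return stop, best


def eliminate(
    importance: ImportanceVector,
    floor_fraction: float,
    min_genes: int = 1,
) -> tuple[list[str], list[str]]:
    """One elimination step: drop genes with non-positive importance.

    If every gene has positive importance, the ``ceil(floor_fraction * d)``
    genes of lowest importance are dropped instead so the loop always makes
    progress. The surviving set never falls below ``min_genes``: when the
    drop list is too long it is truncated, returning the highest-importance
    would-be-dropped genes to the kept set. Returns ``(kept, dropped)`` in
    the original gene order.
    """
    gene_ids = importance.gene_ids
    imp = importance.importance
    d = len(gene_ids)
    if d == 0:
        raise ValueError("importance vector is empty")
    if d <= min_genes:
        return list(gene_ids), []

    drop_mask = imp <= 0
    if not drop_mask.any():
        n_drop = math.ceil(floor_fraction * d)
        order = np.lexsort((np.arange(d), imp))  # lowest importance first, stable
        drop_idx = set(order[:n_drop].tolist())
    else:
        drop_idx = set(np.flatnonzero(drop_mask).tolist())

    max_drop = d - min_genes
    if len(drop_idx) > max_drop:
        # drop only the lowest-importance candidates; the highest-importance
        # would-be-dropped genes return to the kept set
        candidates = sorted(drop_idx, key=lambda i: (imp[i], i))
        drop_idx = set(candidates[:max_drop])

    kept = [g for i, g in enumerate(gene_ids) if i not in drop_idx]
    dropped = [g for i, g in enumerate(gene_ids) if i in drop_idx]
    return kept, dropped


def chunk_first_pass(
    ds: ExpressionDataset, cfg: RunConfig, rng: np.random.Generator | int = 0
) -> list[str]:
    """Screen genes chunk-by-chunk; keep genes with positive importance.

    Genes are randomly permuted and partitioned into near-equal chunks of at
    most ``cfg.chunk_size``; a forest is fitted per chunk and the union of
    positive-importance genes survives, in the original gene order. A no-op
    (all genes returned) when chunking is disabled or the gene count does
    not exceed the chunk size.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    d = ds.n_genes
    if cfg.chunk_size is None or d <= cfg.chunk_size:
        return list(ds.gene_ids)
    n_chunks = math.ceil(d / cfg.chunk_size)
    perm = rng.permutation(d)
    survivors: set[str] = set()
    for chunk in np.array_split(perm, n_chunks):
        ids = [ds.gene_ids[i] for i in sorted(chunk.tolist())]
        sub = ds.subset_genes(ids)
        fst = forest_mod.fit(sub, cfg, rng)
        imp = forest_mod.permutation_importance(fst, sub, rng)
        survivors.update(g for g, v in zip(imp.gene_ids, imp.importance) if v > 0)
    kept = [g for g in ds.gene_ids if g in survivors]
    logger.info("chunked first pass: %d of %d genes survive", len(kept), d)
    return kept


def run_birf(ds: ExpressionDataset, cfg: RunConfig) -> SelectionResult:
    """Full selection run: split, screen, iterate, early-stop, select.

    All randomness derives from ``cfg.seed``; rerunning with the same
    configuration reproduces the result exactly.
    """
    rng = np.random.default_rng(cfg.seed)

    if cfg.validation_fraction > 0:
        train, val = stratified_split(ds, cfg.validation_fraction, rng)
    else:
        train, val = ds, None

    survivors = chunk_first_pass(train, cfg, rng)
    records: list[TraceRecord] = []
    val_errors: list[float] = []
    stop_reason = None
    iteration = 0

    while True:
        iteration += 1
        sub = train.subset_genes(survivors)
        fst = forest_mod.fit(sub, cfg, rng)
        oob = forest_mod.oob_error(fst, sub)
        verr = None
        if val is not None:
            val_sub = val.subset_genes(survivors)
            pred = forest_mod.predict(fst, val_sub)
            verr = float(np.mean(pred != val_sub.encoded_labels()))
        imp = forest_mod.permutation_importance(fst, sub, rng)
        records.append(
            TraceRecord(iteration, tuple(survivors), len(survivors), oob, verr, imp.importance)
        )
        logger.info(
            "iteration %d: n_genes=%d oob_error=%.4f validation_error=%s",
            iteration,
            len(survivors),
            oob,
            "n/a" if verr is None else f"{verr:.4f}",
        )

        if val is not None:
            val_errors.append(verr)
            stop, _ = early_stop(val_errors, cfg.patience)
            if stop:
                stop_reason = "validation_minimum"
                break
        if len(survivors) <= cfg.min_genes and iteration > 1:
            stop_reason = "min_genes_reached"
            break
        kept, dropped = eliminate(imp, cfg.elimination_floor_fraction, cfg.min_genes)
        if not dropped:
            stop_reason = "no_elimination_possible"
            break
        survivors = kept

    # Subset choice: iteration achieving the minimum error. Ties are broken
    # toward the LATEST (smallest) gene set — equal error at fewer genes is
    # the more parsimonious subset, and parsimony is the point of the method.
    # (early_stop's patience clock still runs from the earliest tie.)
    errs = val_errors if val is not None else [r.oob_error for r in records]
    arr = np.asarray(errs)
    best = 1 + int(np.flatnonzero(arr == arr.min())[-1])
    best_rec = records[best - 1]
    order = np.lexsort((np.arange(best_rec.n_genes), -best_rec.importance))
    selected = tuple(best_rec.gene_ids[i] for i in order)

    return SelectionResult(
        selected_genes=selected,
        stop_iteration=iteration,
        stop_reason=stop_reason,
        best_iteration=best,
        trace=IterationTrace(tuple(records)),
        config=cfg,
    )
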