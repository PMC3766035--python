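"""Hold-out evaluation and repeated-run gene-list stability analysis.

Evaluation is confusion-matrix based: overall error is misclassified/total
and per-class accuracy is the diagonal over the row total, matching how
risk-group accuracies are conventionally reported for imbalanced cohorts.

The stability analysis repeats the whole selection with independent derived
seeds (each repeat also re-draws its validation split) and compares the
resulting gene lists: genes that recur across repeats are credibly
informative, genes appearing once are likely chance picks. The headline
statistic ``overlap_at_k`` is Jaccard-style — the intersection of the
repeats' top-k genes over their union — with the plain intersection/k ratio
reported alongside it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import forest as forest_mod
from .data_io import ExpressionDataset, RunConfig
from .selection import SelectionResult, run_birf

__all__ = [
    "ConfusionMatrix",
    "StabilityReport",
    "confusion",
    "error_rate",
    "per_class_accuracy",
    "overlap_at_k",
    "intersection_at_k",
    "stability_runs",
    "holdout_evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K contingency table; rows are actual classes, columns predicted."""

    class_order: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class StabilityReport:
    """Gene lists from repeated runs plus their overlap statistics."""

    n_repeats: int
    gene_lists: tuple[tuple[str, ...], ...]
    core_set: frozenset[str]
    overlap_at_k: dict[int, float]
    intersection_at_k: dict[int, float]
    results: tuple[SelectionResult, ...] = ()


def confusion(actual, predicted, class_order) -> ConfusionMatrix:
    """Count actual-vs-predicted pairs into a K x K matrix."""
    actual = [str(a) for a in actual]
    predicted = [str(p) for p in predicted]
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    if not actual:
        raise ValueError("cannot build a confusion matrix from no samples")
    class_order = tuple(str(c) for c in class_order)
    known = set(class_order)
    for lab in actual + predicted:
        if lab not in known:
            raise ValueError(f"label {lab!r} not in class_order")
    counts = _sk_confusion(actual, predicted, labels=list(class_order))
    return ConfusionMatrix(class_order=class_order, counts=counts)


def error_rate(cm: ConfusionMatrix) -> float:
    """Overall misclassification rate: (total - trace) / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float((cm.total - np.trace(cm.counts)) / cm.total)


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Diagonal over row total per class; NaN where a class has no samples."""
    row_totals = cm.counts.sum(axis=1)
    acc = np.full(len(cm.class_order), np.nan)
    nonzero = row_totals > 0
    acc[nonzero] = np.diag(cm.counts)[nonzero] / row_totals[nonzero]
    return acc


def _topk(gene_list, k: int) -> set[str]:
    return set(list(gene_list)[:k])


def overlap_at_k(gene_lists, k: int) -> float:
    """|intersection of top-k| / |union of top-k| across the lists."""
    tops = [_topk(gl, k) for gl in gene_lists]
    union = set.union(*tops)
    inter = set.intersection(*tops)
    if not union:
        raise ValueError("empty gene lists")
    return len(inter) / len(union)


def intersection_at_k(gene_lists, k: int) -> float:
    """|intersection of top-k| / k across the lists."""
    tops = [_topk(gl, k) for gl in gene_lists]
    inter = set.intersection(*tops)
    return len(inter) / k


def stability_runs(
    ds: ExpressionDataset, cfg: RunConfig, ks: tuple[int, ...] = (20, 100)
) -> StabilityReport:
    """Repeat selection ``cfg.n_repeats`` times with independent derived seeds.

    Each repeat reruns the entire pipeline, including a fresh stratified
    validation split. Overlap statistics are computed for every requested
    ``k`` plus the size of the smallest selected list, each capped at that
    size so top-k is always well defined.
    """
    if cfg.n_repeats < 2:
        raise ValueError("stability analysis needs n_repeats >= 2")
    seed_rng = np.random.default_rng(cfg.seed)
    derived = seed_rng.integers(0, 2**31, size=cfg.n_repeats)
    results = []
    for s in derived:
        results.append(run_birf(ds, dataclasses.replace(cfg, seed=int(s))))
    gene_lists = tuple(r.selected_genes for r in results)
    core = frozenset.intersection(*[frozenset(gl) for gl in gene_lists])
    min_len = min(len(gl) for gl in gene_lists)
    wanted = sorted({min(k, min_len) for k in (*ks, min_len)})
    return StabilityReport(
        n_repeats=cfg.n_repeats,
        gene_lists=gene_lists,
        core_set=core,
        overlap_at_k={k: overlap_at_k(gene_lists, k) for k in wanted},
        intersection_at_k={k: intersection_at_k(gene_lists, k) for k in wanted},
        results=tuple(results),
    )


def holdout_evaluate(
    ds_train: ExpressionDataset,
    ds_test: ExpressionDataset,
    selected_genes,
    cfg: RunConfig,
) -> tuple[ConfusionMatrix, float]:
    """Fit a forest on the selected genes and score an independent test set."""
    selected = list(selected_genes)
    train_sub = ds_train.subset_genes(selected)
    test_sub = ds_test.subset_genes(selected)
    fst = forest_mod.fit(train_sub, cfg, np.random.default_rng(cfg.seed))
    pred_idx = forest_mod.predict(fst, test_sub)
    pred = [fst.class_order[i] for i in pred_idx]
    cm = confusion(test_sub.labels, pred, train_sub.class_order)
    return cm, error_rate(cm)
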