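"""Imbalance-aware random forest: balanced bootstrap, cutoff voting,
out-of-bag error and out-of-bag permutation importance.

Two remedies for severe class imbalance are built in. First, in balanced
mode each tree is grown on a *balanced bootstrap*: n_min cases drawn with
replacement from every class, where n_min is the size of the smallest
class, so no tree is dominated by the majority class. Second, forest-level
class decisions are *cutoff-weighted*: the predicted class is
argmax_k votes_k / cutoff_k, so a small cutoff weight lowers the bar for a
rare class. Individual trees are plain scikit-learn decision trees; the
ensemble logic around them (sampling, voting, OOB accounting, importance)
is what this module provides.

Per-gene importance is OOB permutation importance (mean decrease in
accuracy): for each tree, each gene's values are shuffled among that tree's
out-of-bag samples and the increase in the tree's OOB error is averaged
over trees. A gene never used in any split has importance exactly zero —
the property the elimination rule relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .data_io import ExpressionDataset, RunConfig

__all__ = [
    "BalancedForest",
    "ImportanceVector",
    "NEVER_OOB",
    "balanced_bootstrap",
    "fit",
    "cutoff_vote",
    "oob_predict",
    "oob_error",
    "predict",
    "permutation_importance",
]

logger = logging.getLogger(__name__)

#: Marker returned by :func:`oob_predict` for samples in-bag in every tree.
NEVER_OOB = -1


@dataclass
class ImportanceVector:
    """Per-gene OOB permutation importance, aligned with ``gene_ids``.

    Importance is in units of error-rate increase: the mean over trees of
    the rise in a tree's out-of-bag error when the gene is permuted.
    """

    gene_ids: tuple[str, ...]
    importance: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.importance = np.asarray(self.importance, dtype=float)
        if len(self.gene_ids) != len(self.importance):
            raise ValueError("one importance per gene required")


@dataclass
class BalancedForest:
    """A fitted ensemble with its per-tree in-bag records.

    ``inbag[t]`` holds the training-sample indices drawn for tree ``t``;
    out-of-bag membership is derived from it. ``cutoff`` is the resolved
    K-vector of vote weights in ``class_order``.
    """

    trees: list[DecisionTreeClassifier]
    inbag: list[np.ndarray]
    class_order: tuple[str, ...]
    cutoff: np.ndarray
    mtry: int
    gene_ids: tuple[str, ...]
    n_samples: int
    balance_mode: str = "balanced"
    oob_masks: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.trees) != len(self.inbag):
            raise ValueError("one in-bag record per tree required")
        cut = np.asarray(self.cutoff, dtype=float)
        if len(cut) != len(self.class_order):
            raise ValueError("cutoff length must equal the number of classes")
        if (cut <= 0).any():
            raise ValueError("cutoff entries must be > 0")
        if abs(cut.sum() - 1.0) > 1e-9:
            raise ValueError("cutoff must sum to 1")
        self.cutoff = cut
        if not self.oob_masks:
            self.oob_masks = []
            for bag in self.inbag:
                mask = np.ones(self.n_samples, dtype=bool)
                mask[bag] = False
                self.oob_masks.append(mask)

    @property
    def ntree(self) -> int:
        return len(self.trees)


def balanced_bootstrap(
    labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw a class-balanced bootstrap: n_min cases per class, with replacement.

    ``labels`` are integer class codes. Returns K * n_min sample indices,
    drawn class by class and then shuffled. n_min is the smallest class size,
    so every class contributes equally to the tree grown on the sample.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balanced bootstrap needs at least two non-empty classes")
    n_min = int(counts.min())
    picks = []
    for kls in classes:
        members = np.flatnonzero(labels == kls)
        picks.append(rng.choice(members, size=n_min, replace=True))
    idx = np.concatenate(picks)
    rng.shuffle(idx)
    return idx


def fit(
    ds: ExpressionDataset, cfg: RunConfig, rng: np.random.Generator | int = 0
) -> BalancedForest:
    """Grow ``cfg.ntree`` trees on ``ds`` with the configured sampling mode.

    Each tree is fitted on its own bootstrap — balanced (n_min per class)
    or plain (n draws from all samples) — and considers ``mtry`` random
    genes at each split. In-bag indices are recorded per tree so OOB
    membership is exact. ``mtry`` larger than the gene count is clamped
    with a warning.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.ascontiguousarray(ds.values.T)  # samples x genes
    y = ds.encoded_labels()
    n, d = X.shape
    if not isinstance(cfg.mtry, str) and cfg.mtry > d:
        logger.warning("mtry=%d exceeds gene count %d; clamping", cfg.mtry, d)
    mtry = cfg.resolve_mtry(d)
    cutoff = cfg.resolve_cutoff(ds.class_counts())

    trees: list[DecisionTreeClassifier] = []
    inbag: list[np.ndarray] = []
    for _ in range(cfg.ntree):
        if cfg.balance_mode == "balanced":
            bag = balanced_bootstrap(y, rng)
        else:
            bag = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features=mtry,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(X[bag], y[bag])
        trees.append(tree)
        inbag.append(np.asarray(bag, dtype=np.intp))

    return BalancedForest(
        trees=trees,
        inbag=inbag,
        class_order=ds.class_order,
        cutoff=cutoff,
        mtry=mtry,
        gene_ids=ds.gene_ids,
        n_samples=n,
        balance_mode=cfg.balance_mode,
    )


def cutoff_vote(vote_fractions: np.ndarray, cutoff: np.ndarray) -> int:
    """Class decision argmax_k vote_fractions[k] / cutoff[k].

    Ties go to the smallest class index. With a uniform cutoff this reduces
    to the conventional majority vote.
    """
    votes = np.asarray(vote_fractions, dtype=float)
    cut = np.asarray(cutoff, dtype=float)
    if votes.shape != cut.shape:
        raise ValueError("vote and cutoff vectors must have equal length")
    if (cut <= 0).any():
        raise ValueError("cutoff entries must be > 0")
    return int(np.argmax(votes / cut))


def _tree_predict(tree: DecisionTreeClassifier, X32: np.ndarray) -> np.ndarray:
    """Hard class prediction of one tree, bypassing per-call input validation."""
    proba = tree.tree_.predict(X32)
    if proba.ndim == 3:  # (n_samples, n_outputs, n_classes)
        proba = proba[:, 0, :]
    return tree.classes_[np.argmax(proba, axis=1)]


def _check_genes(forest: BalancedForest, ds: ExpressionDataset) -> None:
    if forest.gene_ids != ds.gene_ids:
        raise ValueError("forest was trained on a different gene set than the dataset")


def _aggregate_votes(
    forest: BalancedForest, counts: np.ndarray, n_votes: np.ndarray
) -> np.ndarray:
    """Turn per-sample vote counts into cutoff-weighted class decisions."""
    pred = np.full(len(counts), NEVER_OOB, dtype=np.intp)
    voted = n_votes > 0
    if voted.any():
        fractions = counts[voted] / n_votes[voted, None]
        ratios = fractions / forest.cutoff[None, :]
        pred[voted] = np.argmax(ratios, axis=1)
    return pred


def oob_predict(forest: BalancedForest, ds: ExpressionDataset) -> np.ndarray:
    """Out-of-bag class prediction per sample.

    For each sample, tree votes are aggregated over the trees whose bootstrap
    excluded it, normalized to fractions, and passed through the cutoff vote.
    Samples in-bag for every tree get :data:`NEVER_OOB` (and are logged);
    with hundreds of trees this is vanishingly rare. Returns integer class
    indices into ``forest.class_order``.
    """
    _check_genes(forest, ds)
    X32 = np.ascontiguousarray(ds.values.T, dtype=np.float32)
    n = X32.shape[0]
    if n != forest.n_samples:
        raise ValueError("dataset sample count differs from the training set")
    K = len(forest.class_order)
    counts = np.zeros((n, K))
    n_votes = np.zeros(n)
    for tree, oob in zip(forest.trees, forest.oob_masks):
        if not oob.any():
            continue
        pred = _tree_predict(tree, X32[oob])
        idx = np.flatnonzero(oob)
        np.add.at(counts, (idx, pred), 1.0)
        n_votes[idx] += 1.0
    never = int((n_votes == 0).sum())
    if never:
        logger.info("%d sample(s) were in-bag for every tree; excluded from OOB error", never)
    return _aggregate_votes(forest, counts, n_votes)


def oob_error(forest: BalancedForest, ds: ExpressionDataset) -> float:
    """Fraction of OOB-predicted samples whose prediction differs from the truth."""
    pred = oob_predict(forest, ds)
    y = ds.encoded_labels()
    voted = pred != NEVER_OOB
    if not voted.any():
        raise ValueError("no sample has an out-of-bag prediction")
    return float(np.mean(pred[voted] != y[voted]))


def predict(forest: BalancedForest, ds: ExpressionDataset) -> np.ndarray:
    """Predict new samples: votes over all trees, then the cutoff vote.

    Returns integer class indices into ``forest.class_order``.
    """
    _check_genes(forest, ds)
    X32 = np.ascontiguousarray(ds.values.T, dtype=np.float32)
    n = X32.shape[0]
    K = len(forest.class_order)
    counts = np.zeros((n, K))
    for tree in forest.trees:
        pred = _tree_predict(tree, X32)
        np.add.at(counts, (np.arange(n), pred), 1.0)
    n_votes = np.full(n, float(forest.ntree))
    return _aggregate_votes(forest, counts, n_votes)


def permutation_importance(
    forest: BalancedForest, ds: ExpressionDataset, rng: np.random.Generator | int = 0
) -> ImportanceVector:
    """OOB permutation importance (mean decrease in accuracy) per gene.

    For each tree: its OOB error is computed from the tree's own hard
    prediction (no cutoff at tree level), then recomputed with one gene's
    values freshly permuted among that tree's OOB samples; the difference
    is the gene's contribution. Genes not used by a tree's splits
    contribute exactly 0 for that tree and are skipped. The final score is
    the mean contribution over all trees.
    """
    _check_genes(forest, ds)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X32 = np.ascontiguousarray(ds.values.T, dtype=np.float32)
    y = ds.encoded_labels()
    d = X32.shape[1]
    total = np.zeros(d)
    for tree, oob in zip(forest.trees, forest.oob_masks):
        n_oob = int(oob.sum())
        if n_oob == 0:
            continue
        Xo = np.ascontiguousarray(X32[oob])
        yo = y[oob]
        base_err = float(np.mean(_tree_predict(tree, Xo) != yo))
        features = tree.tree_.feature
        used = np.unique(features[features >= 0])
        for g in used:
            perm = rng.permutation(n_oob)
            col = Xo[:, g].copy()
            Xo[:, g] = col[perm]
            err = float(np.mean(_tree_predict(tree, Xo) != yo))
            Xo[:, g] = col
            total[g] += err - base_err
    return ImportanceVector(ds.gene_ids, total / forest.ntree)
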