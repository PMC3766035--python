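"""Synthetic imbalanced expression data with planted informative genes.

The generator emulates the regime the method targets: a few hundred samples,
thousands of genes, 2-8 classes with severe imbalance (e.g. a 53/11/6
training cohort), and a small planted set of class-informative genes amid
i.i.d. Gaussian noise genes. Noise is Normal(0, sd^2), matching continuous
normalized microarray intensities; each planted gene receives a per-class
mean offset of ``effect_size * noise_sd * u`` with u in {-1, 0, +1} drawn
per (gene, class), so different planted genes separate different subsets of
classes — including minority-only markers, the setting the balanced
bootstrap exists for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import ExpressionDataset

__all__ = ["SimSpec", "simulate", "stratified_split"]


@dataclass(frozen=True)
class SimSpec:
    """Specification of one simulated cohort.

    Attributes
    ----------
    n_per_class : sequence of int
        Sample count per class; its length sets K.
    n_genes : int
        Total genes, noise plus planted.
    n_informative : int
        Planted class-informative genes.
    effect_size : float
        Between-class mean shift for planted genes, in noise-SD units.
    noise_sd : float
        Standard deviation of every gene's noise component.
    seed : int
        Seed for the generator; identical specs yield identical data.
    """

    n_per_class: tuple[int, ...]
    n_genes: int
    n_informative: int
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_class", tuple(int(n) for n in self.n_per_class))
        if len(self.n_per_class) < 2:
            raise ValueError("at least two classes required")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("every class needs at least one sample")
        if self.n_genes < 1 or self.n_informative < 0:
            raise ValueError("counts must be positive")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def simulate(spec: SimSpec) -> tuple[ExpressionDataset, set[str]]:
    """Draw one dataset from ``spec``; returns it with the planted gene ids.

    Every gene is i.i.d. Normal(0, noise_sd^2) across samples; planted genes
    additionally get a class-specific mean offset (see module docstring).
    The per-(gene, class) offset signs are redrawn until at least two
    classes differ, so every planted gene carries real class signal.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.n_per_class)
    n = sum(spec.n_per_class)
    digits = max(1, len(str(spec.n_genes)))
    gene_ids = tuple(f"G{i:0{digits}d}" for i in range(1, spec.n_genes + 1))
    sample_ids = tuple(f"S{i:03d}" for i in range(1, n + 1))
    class_names = tuple(f"C{j + 1}" for j in range(k))
    labels = tuple(
        class_names[j] for j, cnt in enumerate(spec.n_per_class) for _ in range(cnt)
    )
    y = np.repeat(np.arange(k), spec.n_per_class)

    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    planted_idx = rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    planted_idx.sort()
    for g in planted_idx:
        u = rng.integers(-1, 2, size=k)
        while len(set(u.tolist())) < 2:
            u = rng.integers(-1, 2, size=k)
        values[g, :] += spec.effect_size * spec.noise_sd * u[y]

    ds = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        labels=labels,
        class_order=class_names,
    )
    return ds, {gene_ids[g] for g in planted_idx}


def stratified_split(
    ds: ExpressionDataset, fraction: float, seed: int | np.random.Generator
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Split samples into (train, held_out) preserving class proportions.

    Per class, round-half-even ``round(fraction * n_k)`` samples are held
    out, clamped so both parts keep at least one sample of every class.
    The parts are disjoint and exhaustive; the gene set is untouched.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = ds.encoded_labels()
    train_idx: list[int] = []
    held_idx: list[int] = []
    for kls, name in enumerate(ds.class_order):
        members = np.flatnonzero(y == kls)
        n_k = len(members)
        if n_k < 2:
            raise ValueError(
                f"class {name!r} has {n_k} sample(s); need >= 2 to stratify"
            )
        n_held = int(round(fraction * n_k))  # Python round: half-to-even
        n_held = min(max(n_held, 1), n_k - 1)
        picked = rng.choice(members, size=n_held, replace=False)
        held = set(picked.tolist())
        held_idx.extend(sorted(held))
        train_idx.extend(int(i) for i in members if int(i) not in held)
    return ds.subset_samples(sorted(train_idx)), ds.subset_samples(sorted(held_idx))


def holdout_counts(n_per_class: Sequence[int], fraction: float) -> list[int]:
    """Held-out count per class under the split's rounding and clamping rules."""
    out = []
    for n_k in n_per_class:
        n_held = int(round(fraction * n_k))
        out.append(min(max(n_held, 1), n_k - 1))
    return out
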