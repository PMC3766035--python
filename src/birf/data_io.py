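"""Expression-matrix and label I/O, run configuration, and result serialization.

The on-disk convention is plain delimited text: an expression matrix with
gene identifiers in the first column and sample identifiers in the header
row (genes-in-rows, the microarray convention; an orientation flag covers
samples-in-rows exports), plus a two-column sample→label table. Gene and
sample identifiers are treated as opaque strings.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionDataset",
    "RunConfig",
    "read_expression",
    "write_expression",
    "write_selection",
    "read_trace",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """A labelled numeric expression matrix (genes x samples).

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers, one per gene.
    sample_ids : sequence of str
        Unique column identifiers, one per sample.
    values : ndarray, shape (n_genes, n_samples)
        Expression values; units are whatever the upstream normalization
        produced (the method is rank/threshold free, so units are arbitrary).
    labels : sequence of str
        Class label per sample, aligned with ``sample_ids``.
    class_order : tuple of str, optional
        Fixed ordering of the K distinct classes. Defaults to the
        lexicographic sort of the observed labels so that cutoff vectors
        and confusion matrices are reproducible regardless of file order.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    labels: tuple[str, ...]
    class_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one label per sample required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValueError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValueError(f"duplicate sample id {dup!r}")
        if np.isnan(values).any():
            g, s = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if not self.class_order:
            object.__setattr__(self, "class_order", tuple(sorted(set(self.labels))))
        else:
            object.__setattr__(self, "class_order", tuple(str(c) for c in self.class_order))
        observed = set(self.labels)
        declared = set(self.class_order)
        if not observed <= declared:
            raise ValueError(f"labels {sorted(observed - declared)} not in class_order")
        if not declared <= observed:
            raise ValueError(f"classes {sorted(declared - observed)} have no samples")
        if len(self.class_order) < 2:
            raise ValueError("at least two classes required")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def class_counts(self) -> np.ndarray:
        """Number of samples per class, in ``class_order``."""
        idx = self.encoded_labels()
        return np.bincount(idx, minlength=self.n_classes)

    def encoded_labels(self) -> np.ndarray:
        """Labels as integer indices into ``class_order``."""
        lut = {c: k for k, c in enumerate(self.class_order)}
        return np.array([lut[l] for l in self.labels], dtype=np.intp)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the given genes (kept in the given order)."""
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [lut[g] for g in gene_ids]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in dataset") from None
        return ExpressionDataset(
            gene_ids=tuple(gene_ids),
            sample_ids=self.sample_ids,
            values=self.values[rows, :],
            labels=self.labels,
            class_order=self.class_order,
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        """Restrict to the given sample positions (kept in the given order)."""
        idx = np.asarray(indices, dtype=np.intp)
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            values=self.values[:, idx],
            labels=tuple(self.labels[i] for i in idx),
            class_order=self.class_order,
        )

    def to_frame(self) -> pd.DataFrame:
        """Genes-in-rows DataFrame view (index = gene ids, columns = sample ids)."""
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""  # pragma: no cover


@dataclass
class RunConfig:
    """Tunable parameters for one feature-selection run.

    Attributes
    ----------
    ntree : int
        Trees per forest (default 500).
    mtry : int or "sqrt"
        Candidate genes per split; "sqrt" resolves to ceil(sqrt(d)) for the
        current gene count d, the classification default of the reference
        forest implementation.
    chunk_size : int or None
        First-iteration gene-chunk size; None disables chunking.
    validation_fraction : float
        Fraction of samples held out (stratified) to drive early stopping;
        0 disables the validation split and selection falls back to the
        smallest-OOB-error subset.
    patience : int
        Consecutive non-improving iterations tolerated after the running
        validation-error minimum before stopping.
    min_genes : int
        Elimination never reduces the surviving set below this size.
    balance_mode : {"balanced", "plain"}
        Balanced per-class bootstrap vs conventional bootstrap of size n.
    cutoff : "uniform", "prior", or sequence of float
        Per-class vote weights; votes are divided by the cutoff before the
        argmax, so small weights favour rare classes.
    seed : int
        Master seed; every stream of randomness derives from it.
    n_repeats : int
        Number of repeated runs in the stability analysis.
    elimination_floor_fraction : float
        When no gene has non-positive importance, the lowest
        ceil(fraction * d) genes are dropped instead (progress guarantee).
    """

    ntree: int = 500
    mtry: int | str = "sqrt"
    chunk_size: int | None = 2000
    validation_fraction: float = 0.25
    patience: int = 3
    min_genes: int = 2
    balance_mode: str = "balanced"
    cutoff: str | Sequence[float] = "uniform"
    seed: int = 0
    n_repeats: int = 3
    elimination_floor_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be positive")
        if isinstance(self.mtry, str):
            if self.mtry != "sqrt":
                raise ValueError("mtry must be a positive integer or 'sqrt'")
        elif self.mtry < 1:
            raise ValueError("mtry must be positive")
        if self.chunk_size is not None and self.chunk_size < 1:
            raise ValueError("chunk_size must be positive or None")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if self.balance_mode not in ("balanced", "plain"):
            raise ValueError("balance_mode must be 'balanced' or 'plain'")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0 < self.elimination_floor_fraction < 1:
            raise ValueError("elimination_floor_fraction must lie in (0, 1)")
        if not isinstance(self.cutoff, str):
            cut = np.asarray(list(self.cutoff), dtype=float)
            if (cut <= 0).any():
                raise ValueError("explicit cutoff entries must be > 0")
            if abs(cut.sum() - 1.0) > 1e-9:
                raise ValueError("explicit cutoff must sum to 1")
            self.cutoff = tuple(float(c) for c in cut)
        elif self.cutoff not in ("uniform", "prior"):
            raise ValueError("cutoff must be 'uniform', 'prior', or an explicit vector")

    def resolve_mtry(self, n_genes: int) -> int:
        """Concrete per-split candidate count for a forest on ``n_genes`` genes."""
        if self.mtry == "sqrt":
            return max(1, math.ceil(math.sqrt(n_genes)))
        return min(int(self.mtry), n_genes)

    def resolve_cutoff(self, class_counts: np.ndarray) -> np.ndarray:
        """Concrete K-vector of vote weights for the given class counts."""
        k = len(class_counts)
        if isinstance(self.cutoff, str):
            if self.cutoff == "uniform":
                cut = np.full(k, 1.0 / k)
            else:  # prior
                cut = np.asarray(class_counts, dtype=float)
                cut /= cut.sum()
        else:
            cut = np.asarray(self.cutoff, dtype=float)
            if len(cut) != k:
                raise ValueError(f"cutoff has {len(cut)} entries for {k} classes")
        if (cut <= 0).any():
            raise ValueError("resolved cutoff entries must be > 0")
        return cut

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["cutoff"], tuple):
            d["cutoff"] = list(d["cutoff"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def _sniff_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    genes_in: str = "rows",
) -> ExpressionDataset:
    """Load an expression matrix and its sample labels.

    Parameters
    ----------
    matrix_path
        CSV/TSV with identifiers in the first column and a header row.
    labels_path
        Two-column CSV/TSV mapping sample id -> class label; a header row
        is detected and skipped if its first field is ``sample_id``.
    genes_in : {"rows", "columns"}
        Orientation of the matrix file. Internally the dataset is always
        genes x samples.
    """
    matrix_path = Path(matrix_path)
    labels_path = Path(labels_path)
    if genes_in not in ("rows", "columns"):
        raise ValueError("genes_in must be 'rows' or 'columns'")

    frame = pd.read_csv(matrix_path, sep=_sniff_sep(matrix_path), index_col=0)
    if genes_in == "columns":
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)

    non_numeric = frame.columns[
        [not pd.api.types.is_numeric_dtype(frame[c]) for c in frame.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad_row = frame.index[coerced.isna() & frame[col].notna()]
        where = bad_row[0] if len(bad_row) else "?"
        raise ValueError(
            f"non-numeric expression value at gene {where!r}, sample {col!r}"
        )
    if frame.isna().any().any():
        g = frame.index[frame.isna().any(axis=1)][0]
        s = frame.columns[frame.isna().any(axis=0)][0]
        raise ValueError(f"missing value at gene {g!r}, sample {s!r}")

    labels_map = _read_labels(labels_path)
    missing = [s for s in frame.columns if s not in labels_map]
    if missing:
        raise ValueError(f"sample {missing[0]!r} has no entry in the label file")

    return ExpressionDataset(
        gene_ids=tuple(frame.index),
        sample_ids=tuple(frame.columns),
        values=frame.to_numpy(dtype=float),
        labels=tuple(labels_map[s] for s in frame.columns),
    )


def _read_labels(path: Path) -> dict[str, str]:
    table = pd.read_csv(path, sep=_sniff_sep(path), header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (sample_id, label)")
    table = table.iloc[:, :2]
    if str(table.iloc[0, 0]).lower() in ("sample_id", "sample", "id"):
        table = table.iloc[1:]
    dup = table.iloc[:, 0][table.iloc[:, 0].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample id {dup.iloc[0]!r} in label file")
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def write_expression(
    ds: ExpressionDataset, matrix_path: str | Path, labels_path: str | Path
) -> None:
    """Write a dataset back to matrix + label files (genes in rows)."""
    matrix_path = Path(matrix_path)
    labels_path = Path(labels_path)
    ds.to_frame().to_csv(matrix_path, sep=_sniff_sep(matrix_path))
    pd.DataFrame({"sample_id": list(ds.sample_ids), "label": list(ds.labels)}).to_csv(
        labels_path, sep=_sniff_sep(labels_path), index=False, header=False
    )


def write_selection(result, out_dir: str | Path) -> None:
    """Persist a :class:`~birf.selection.SelectionResult` to a directory.

    Emits ``selected_genes.txt`` (one id per line, importance order),
    ``trace.tsv`` (iteration, n_genes, oob_error, validation_error) and
    ``config.yaml`` (the fully resolved configuration including the seed),
    which together reproduce the run bit-for-bit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "selected_genes.txt").write_text(
        "".join(f"{g}\n" for g in result.selected_genes)
    )
    rows = []
    for rec in result.trace.records:
        rows.append(
            {
                "iteration": rec.iteration,
                "n_genes": rec.n_genes,
                "oob_error": rec.oob_error,
                "validation_error": "" if rec.validation_error is None else rec.validation_error,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "trace.tsv", sep="\t", index=False)
    meta = result.config.to_dict()
    meta["stop_iteration"] = result.stop_iteration
    meta["stop_reason"] = result.stop_reason
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_trace(path: str | Path) -> pd.DataFrame:
    """Read a trace table written by :func:`write_selection`."""
    return pd.read_csv(path, sep="\t")
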