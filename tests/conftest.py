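import numpy as np
import pytest

from birf import ExpressionDataset, RunConfig, SimSpec, simulate


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, two classes, hand-written values."""
    return ExpressionDataset(
        gene_ids=("g1", "g2", "g3"),
        sample_ids=("s1", "s2", "s3", "s4"),
        values=np.array(
            [[1.0, 2.0, 3.0, 4.0], [0.5, 0.5, 2.5, 2.5], [0.0, 0.1, 0.0, 0.1]]
        ),
        labels=("A", "A", "B", "B"),
    )


@pytest.fixture
def small_sim():
    """60 samples x 80 genes, 2 classes 40/20, 8 strong planted genes."""
    ds, planted = simulate(
        SimSpec(n_per_class=(40, 20), n_genes=80, n_informative=8, effect_size=3.0, seed=11)
    )
    return ds, planted


@pytest.fixture
def fast_cfg():
    return RunConfig(ntree=60, seed=5, chunk_size=None)


@pytest.fixture
def matrix_files(tmp_path, tiny_dataset):
    """The tiny dataset written out as matrix + label files."""
    matrix = tmp_path / "expr.csv"
    labels = tmp_path / "labels.tsv"
    frame = tiny_dataset.to_frame()
    frame.to_csv(matrix)
    labels.write_text(
        "".join(f"{s}\t{l}\n" for s, l in zip(tiny_dataset.sample_ids, tiny_dataset.labels))
    )
    return matrix, labels
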