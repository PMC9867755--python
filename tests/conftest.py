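import numpy as np
import pytest

from retorg.config import PipelineConfig
from retorg.datatypes import CellTable, normalize_fraction_umi
from retorg.simulate import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def synth_default():
    """One default synthetic dataset shared across tests (seed fixed)."""
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def synth_expr(synth_default):
    table, _ = synth_default
    return normalize_fraction_umi(table)


@pytest.fixture()
def params():
    return PipelineConfig(rng_seed=11)


def make_cell_table(counts, *, condition=None, stage=None, cell_type=None,
                    cluster=None, embedding=None):
    """Small hand-rolled CellTable with sensible defaults for the rest."""
    counts = np.asarray(counts)
    n, g = counts.shape
    return CellTable(
        counts=counts,
        gene_ids=[f"g{j}" for j in range(g)],
        cell_ids=[f"c{i}" for i in range(n)],
        condition=np.array(condition if condition is not None
                           else ["native"] * n, dtype=object),
        stage=np.array(stage if stage is not None else ["I"] * n, dtype=object),
        cluster=np.asarray(cluster if cluster is not None else np.zeros(n, int)),
        cell_type=np.array(cell_type if cell_type is not None
                           else ["NE"] * n, dtype=object),
        embedding=np.asarray(embedding if embedding is not None
                             else np.zeros((n, 2))),
    )


@pytest.fixture()
def tiny_bundle(tmp_path):
    """Write a 3-cell x 2-gene MTX bundle plus metadata; return the paths."""
    counts = np.array([[1, 2], [0, 3], [4, 0]])  # cells x genes
    mtx = tmp_path / "matrix.mtx"
    lines = ["%%MatrixMarket matrix coordinate integer general",
             "2 3 4"]  # genes x cells
    for ci in range(3):
        for gi in range(2):
            if counts[ci, gi]:
                lines.append(f"{gi + 1} {ci + 1} {counts[ci, gi]}")
    mtx.write_text("\n".join(lines) + "\n")
    (tmp_path / "genes.tsv").write_text("gA\tgA\ngB\tgB\n")
    (tmp_path / "barcodes.tsv").write_text("bc1\nbc2\nbc3\n")
    (tmp_path / "metadata.tsv").write_text(
        "barcode\tcondition\tstage\tcluster\tcell_type\tx\ty\n"
        "bc1\tnative\tI\t0\tNE\t0.0\t0.0\n"
        "bc2\tnative\tII\t0\tNE\t1.0\t0.5\n"
        "bc3\torganoid\tI\t1\tRGC\t2.0\t1.5\n"
    )
    return {
        "matrix": mtx,
        "genes": tmp_path / "genes.tsv",
        "barcodes": tmp_path / "barcodes.tsv",
        "metadata": tmp_path / "metadata.tsv",
        "counts": counts,
    }
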