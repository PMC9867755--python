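"""Readers and writers for the 10x-style MTX bundle, gene lists and GMT files.

The count matrix is stored genes x cells in MatrixMarket format (the 10x v2
convention) next to ``genes.tsv`` and ``barcodes.tsv``; it is transposed to
cells x genes on load.  Per-cell metadata travels in a separate TSV keyed by
barcode with columns ``condition``, ``stage``, ``cluster`` and optionally
``cell_type``, ``x``, ``y``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from retorg.datatypes import (
    CellTable,
    FormatError,
    GeneList,
    NOT_IDENTIFIED,
    ValidationError,
)
from retorg.enrichment import GeneSetCollection

log = logging.getLogger(__name__)


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def load_cell_table(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    metadata_path: str | Path,
) -> CellTable:
    """Load a counts bundle plus metadata TSV into a validated CellTable.

    Raises
    ------
    FormatError
        if the MTX dimensions disagree with the gene/barcode files.
    ValidationError
        if a barcode lacks a metadata row or labels are out of vocabulary.
    """
    matrix = scipy.io.mmread(matrix_path)
    if scipy.sparse.issparse(matrix):
        matrix = matrix.toarray()
    matrix = np.asarray(matrix)
    genes = _read_lines(genes_path)
    barcodes = _read_lines(barcodes_path)
    n_genes, n_cells = matrix.shape
    if n_genes != len(genes):
        raise FormatError(
            f"matrix declares {n_genes} genes but {genes_path} lists {len(genes)}"
        )
    if n_cells != len(barcodes):
        raise FormatError(
            f"matrix declares {n_cells} cells but {barcodes_path} lists {len(barcodes)}"
        )
    counts = np.rint(matrix.T).astype(np.int64)

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"barcode": str})
    required = {"barcode", "condition", "stage", "cluster"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise FormatError(
            f"{metadata_path}: missing metadata columns {sorted(missing_cols)}"
        )
    meta = meta.set_index("barcode")
    absent = [bc for bc in barcodes if bc not in meta.index]
    if absent:
        raise ValidationError(
            f"barcodes without metadata rows: {absent[:10]}"
            + (" ..." if len(absent) > 10 else "")
        )
    meta = meta.loc[barcodes]

    if "cell_type" in meta.columns:
        cell_type = meta["cell_type"].fillna(NOT_IDENTIFIED).to_numpy(dtype=object)
    else:
        cell_type = np.full(n_cells, NOT_IDENTIFIED, dtype=object)
    if {"x", "y"} <= set(meta.columns):
        embedding = meta[["x", "y"]].to_numpy(dtype=float)
    else:
        embedding = np.zeros((n_cells, 2))
    return CellTable(
        counts=counts,
        gene_ids=genes,
        cell_ids=barcodes,
        condition=meta["condition"].to_numpy(dtype=object),
        stage=meta["stage"].to_numpy(dtype=object),
        cluster=meta["cluster"].to_numpy(dtype=np.int64),
        cell_type=cell_type,
        embedding=embedding,
    )


def write_cell_table(table: CellTable, outdir: str | Path) -> dict[str, Path]:
    """Write the standard bundle (matrix.mtx, genes.tsv, barcodes.tsv,
    metadata.tsv) and return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "genes": outdir / "genes.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "metadata": outdir / "metadata.tsv",
    }
    scipy.io.mmwrite(
        paths["matrix"], scipy.sparse.csr_matrix(table.counts.T), field="integer"
    )
    paths["genes"].write_text("".join(f"{g}\t{g}\n" for g in table.gene_ids))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in table.cell_ids))
    table.metadata_frame().to_csv(paths["metadata"], sep="\t")
    return paths


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a one-gene-per-line list (e.g. a TF catalogue or disease genes)."""
    genes = _read_lines(path)
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    return GeneList(name=name or Path(path).stem, genes=frozenset(genes))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in Broad GMT dialect: name, description, genes...

    Duplicate genes within a set are collapsed; empty sets are dropped with
    a warning.  A line with fewer than three tab-separated fields is a
    format error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                log.warning("dropping empty gene set %r (line %d)", name, lineno)
                continue
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)
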