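"""Core in-memory containers shared by every pipeline stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 13 canonical retinal cell types, in their fixed display order:
#: neuroepithelium, retinal pigmented epithelium, early/late/neurogenic
#: retinal progenitors, retinal ganglion cells, horizontal cells, amacrine
#: cells, photoreceptor precursors, cones, rods, bipolar cells, Muller glia.
CELL_TYPES: tuple[str, ...] = (
    "NE", "RPE", "ERPC", "LRPC", "NRPC", "RGC", "HC",
    "AC", "PRP", "C", "R", "BP", "MC",
)

#: Label used for cells/clusters whose type could not be identified.
NOT_IDENTIFIED = "NI"

STAGES: tuple[str, ...] = ("I", "II", "III", "IV")
CONDITIONS: tuple[str, ...] = ("native", "organoid")


class ValidationError(ValueError):
    """Input violates a semantic contract (labels, shapes, parameter ranges)."""


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


@dataclass
class CellTable:
    """A cells x genes UMI count matrix with per-cell metadata.

    Parameters
    ----------
    counts
        Dense integer array, one row per cell, one column per gene.
    gene_ids
        Gene symbols, unique, one per column.
    cell_ids
        Cell barcodes, unique, one per row.
    condition
        Per-cell label in ``{"native", "organoid"}``.
    stage
        Per-cell developmental stage in ``{"I", "II", "III", "IV"}``.
    cluster
        Per-cell integer cluster id (taken as given; clustering itself is
        upstream of this package).
    cell_type
        Per-cell label among the 13 canonical types or ``"NI"``.
    embedding
        (n_cells, 2) array of 2D embedding coordinates (e.g. UMAP).
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    condition: np.ndarray
    stage: np.ndarray
    cluster: np.ndarray
    cell_type: np.ndarray
    embedding: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2D cells x genes matrix")
        n_cells, n_genes = self.counts.shape
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValidationError("counts must be integers (UMI counts)")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} count columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene symbols must be unique")
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} barcodes for {n_cells} count rows"
            )
        for name in ("condition", "stage", "cluster", "cell_type"):
            vec = np.asarray(getattr(self, name))
            if vec.shape != (n_cells,):
                raise ValidationError(f"{name} must have one entry per cell")
            setattr(self, name, vec)
        bad = sorted(set(self.condition) - set(CONDITIONS))
        if bad:
            raise ValidationError(f"unknown condition labels: {bad}")
        bad = sorted(set(self.stage) - set(STAGES))
        if bad:
            raise ValidationError(f"unknown stage labels: {bad}")
        bad = sorted(set(self.cell_type) - set(CELL_TYPES) - {NOT_IDENTIFIED})
        if bad:
            raise ValidationError(f"unknown cell_type labels: {bad}")
        self.embedding = np.asarray(self.embedding, dtype=float)
        if self.embedding.shape != (n_cells, 2):
            raise ValidationError("embedding must be an (n_cells, 2) array")
        if not np.isfinite(self.embedding).all():
            raise ValidationError("embedding coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def metadata_frame(self) -> pd.DataFrame:
        """Per-cell metadata as a DataFrame indexed by barcode."""
        return pd.DataFrame(
            {
                "condition": self.condition,
                "stage": self.stage,
                "cluster": self.cluster,
                "cell_type": self.cell_type,
                "x": self.embedding[:, 0],
                "y": self.embedding[:, 1],
            },
            index=pd.Index(self.cell_ids, name="barcode"),
        )

    def subset_cells(self, mask: np.ndarray) -> "CellTable":
        """Return a new table restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellTable(
            counts=self.counts[idx],
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in idx],
            condition=self.condition[idx],
            stage=self.stage[idx],
            cluster=self.cluster[idx],
            cell_type=self.cell_type[idx],
            embedding=self.embedding[idx],
        )


@dataclass
class ExpressionMatrix:
    """Per-cell expression as fraction of total UMI.

    Each row of ``values`` is the cell's counts divided by its total UMI
    count, so rows of cells with at least one count sum to 1.  Cells with
    zero total counts keep an all-zero row and are flagged in
    ``zero_count_cells``; every downstream statistic excludes them.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    zero_count_cells: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    source: CellTable | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2D cells x genes")
        if self.zero_count_cells.size == 0:
            self.zero_count_cells = np.zeros(self.values.shape[0], dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def gene_index(self, genes: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass(frozen=True)
class GeneList:
    """A named set of gene symbols (e.g. a TF catalogue or disease-gene list)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene list {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def normalize_fraction_umi(table: CellTable) -> ExpressionMatrix:
    """Convert UMI counts to per-cell fraction-of-UMI expression.

    Every gene's value in a cell is its count divided by the cell's total
    count.  Cells with zero total counts get an all-zero row and are
    flagged rather than dropped.
    """
    if table.n_genes < 1:
        raise ValidationError("need at least one gene")
    totals = table.counts.sum(axis=1).astype(float)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    values = table.counts / safe[:, None]
    return ExpressionMatrix(
        values=values,
        gene_ids=list(table.gene_ids),
        cell_ids=list(table.cell_ids),
        zero_count_cells=zero,
        source=table,
    )
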