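"""Cross-dataset comparison of per-gene expression profiles.

A profile is a gene's mean fraction-of-UMI across the 13 canonical cell
types.  Comparing two datasets (e.g. native retina vs organoid, or two
species linked by an ortholog table) reduces to per-gene Pearson
correlation of the two profiles over their shared cell types, summarized
by the median r and the number of genes above a conservation threshold
(0.60 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from retorg.datatypes import CELL_TYPES, ExpressionMatrix, GeneList, ValidationError

log = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Genes x cell types mean expression (fraction of UMI)."""

    values: pd.DataFrame  # index = genes, columns = cell types
    dropped_genes: list[str]
    omitted_types: list[str]


@dataclass
class CorrelationSummary:
    per_gene: pd.Series  # Pearson r per gene, over common cell types
    median_r: float
    n_above: int
    percent_above: float
    threshold: float
    n_zero_variance: int


def mean_profile_matrix(
    expr: ExpressionMatrix,
    cell_type: np.ndarray,
    genes: GeneList,
) -> ProfileMatrix:
    """Per (gene, type) mean fraction-of-UMI for the requested genes.

    Genes absent from the data are dropped with a logged name; canonical
    types with zero cells are omitted and recorded.
    """
    cell_type = np.asarray(cell_type)
    usable = ~expr.zero_count_cells
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    wanted = sorted(genes.genes)
    present = [g for g in wanted if g in gene_pos]
    dropped = [g for g in wanted if g not in gene_pos]
    for g in dropped:
        log.warning("profile gene %s absent from data; dropped", g)
    if not present:
        raise ValidationError("none of the requested genes are present")
    cols = {}
    omitted = []
    for ctype in CELL_TYPES:
        mask = usable & (cell_type == ctype)
        if not mask.any():
            omitted.append(ctype)
            continue
        sub = expr.values[mask][:, [gene_pos[g] for g in present]]
        cols[ctype] = sub.mean(axis=0)
    frame = pd.DataFrame(cols, index=present)
    return ProfileMatrix(values=frame, dropped_genes=dropped, omitted_types=omitted)


def profile_correlation(
    a: ProfileMatrix,
    b: ProfileMatrix,
    r_threshold: float = 0.60,
    method: str = "pearson",
    log_transform: bool = False,
) -> CorrelationSummary:
    """Per-gene correlation of two profile matrices over common columns.

    Genes with zero variance in either profile are excluded (and counted)
    rather than assigned r = 0.  ``method`` may be "pearson" (default) or
    "spearman"; ``log_transform`` applies log1p to both matrices first.
    """
    common_cols = [c for c in a.values.columns if c in b.values.columns]
    if len(common_cols) < 3:
        raise ValidationError(
            f"need >= 3 common cell-type columns, got {len(common_cols)}"
        )
    common_genes = [g for g in a.values.index if g in set(b.values.index)]
    if not common_genes:
        raise ValidationError("no common genes between the profile matrices")
    A = a.values.loc[common_genes, common_cols].to_numpy(dtype=float)
    B = b.values.loc[common_genes, common_cols].to_numpy(dtype=float)
    if log_transform:
        A, B = np.log1p(A), np.log1p(B)
    var_a = A.var(axis=1)
    var_b = B.var(axis=1)
    ok = (var_a > 0) & (var_b > 0)
    n_zero = int((~ok).sum())
    rs = {}
    for i, gene in enumerate(common_genes):
        if not ok[i]:
            continue
        if method == "pearson":
            r = np.corrcoef(A[i], B[i])[0, 1]
        elif method == "spearman":
            from scipy.stats import spearmanr

            r = spearmanr(A[i], B[i]).statistic
        else:
            raise ValidationError(f"unknown correlation method {method!r}")
        rs[gene] = float(r)
    per_gene = pd.Series(rs, name="r")
    if per_gene.empty:
        raise ValidationError("every common gene has a zero-variance profile")
    n_above = int((per_gene > r_threshold).sum())
    return CorrelationSummary(
        per_gene=per_gene,
        median_r=float(per_gene.median()),
        n_above=n_above,
        percent_above=round(100.0 * n_above / len(per_gene), 1),
        threshold=r_threshold,
        n_zero_variance=n_zero,
    )
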