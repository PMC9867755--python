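"""Marker-signature scoring: cell-type annotation and cell-cycle phase.

A signature score is the mean, over the signature's genes, of gene-wise
z-scores of log1p(scale * fraction-of-UMI) expression (population z-scores
across cells; zero-variance genes contribute 0).  Cluster scores average
the cell scores within the cluster.  A cluster's type is the arg-max
signature among the 13 canonical types, demoted to "NI" when the top score
is negative or the winning margin is too small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from retorg.datatypes import (
    CELL_TYPES,
    NOT_IDENTIFIED,
    ExpressionMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Default log-normalization scale (counts-per-10k convention).
DEFAULT_SCALE = 1e4


@dataclass
class SignatureSet:
    """Named marker-gene signatures: the 13 cell types and, optionally,
    subpopulations (T1/T2/T3, CMZ, Tbr1+RGC) and cycle phases (S, G2-M)."""

    signatures: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, genes in self.signatures.items():
            if not genes:
                raise ValidationError(f"signature {name!r} is empty")
        self.signatures = {k: frozenset(v) for k, v in self.signatures.items()}

    @property
    def names(self) -> list[str]:
        return list(self.signatures)

    def subset(self, names) -> "SignatureSet":
        return SignatureSet({n: self.signatures[n] for n in names})


@dataclass
class ScoreMatrix:
    """Rows = clusters (or cells), columns = signatures."""

    values: pd.DataFrame
    by: str = "cluster"
    ties: list[tuple] = field(default_factory=list)


def _log_normalized(expr: ExpressionMatrix, scale: float) -> np.ndarray:
    return np.log1p(scale * expr.values)


def score_signatures(
    expr: ExpressionMatrix,
    sigs: SignatureSet,
    by: str = "cluster",
    cluster: np.ndarray | None = None,
    scale: float = DEFAULT_SCALE,
) -> ScoreMatrix:
    """Score every signature for every cell (or cluster).

    Gene-wise z-scores are computed across all usable cells of
    log1p(scale * fraction); a signature's score is the mean z over its
    genes present in the data; cluster scores are cell-score means.
    """
    if by not in ("cluster", "cell"):
        raise ValidationError("by must be 'cluster' or 'cell'")
    if by == "cluster":
        if cluster is None:
            raise ValidationError("cluster labels required when by='cluster'")
        cluster = np.asarray(cluster)
    usable = ~expr.zero_count_cells
    logex = _log_normalized(expr, scale)[usable]
    mu = logex.mean(axis=0)
    sd = logex.std(axis=0)  # population SD; zero-variance genes -> z = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (logex - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    cols = {}
    for name, genes in sigs.signatures.items():
        present = [gene_pos[g] for g in sorted(genes) if g in gene_pos]
        missing = len(genes) - len(present)
        if not present:
            raise ValidationError(
                f"signature {name!r}: none of its genes are in the data"
            )
        if missing:
            log.warning("signature %s: %d gene(s) missing from data", name, missing)
        cols[name] = z[:, present].mean(axis=1)
    cell_scores = pd.DataFrame(
        cols, index=np.asarray(expr.cell_ids, dtype=object)[usable]
    )
    if by == "cell":
        return ScoreMatrix(values=cell_scores, by="cell")
    frame = cell_scores.groupby(cluster[usable]).mean()
    frame.index.name = "cluster"
    return ScoreMatrix(values=frame, by="cluster")


def assign_cell_types(scores: ScoreMatrix, margin_min: float = 0.05) -> pd.Series:
    """Assign each cluster to one of the 13 types or NI.

    Label = arg-max score among the canonical types; NI when the top score
    is negative or the top-minus-second margin is below ``margin_min``.
    Exact ties go to the earlier signature in canonical order and are
    logged.
    """
    if scores.by != "cluster":
        raise ValidationError("cell-type assignment expects cluster-level scores")
    type_cols = [c for c in CELL_TYPES if c in scores.values.columns]
    if len(type_cols) < 2:
        raise ValidationError("need signatures for at least two cell types")
    frame = scores.values[type_cols]
    labels = {}
    for cluster_id, row in frame.iterrows():
        vals = row.to_numpy()
        order = np.argsort(-vals, kind="stable")  # stable: ties -> earlier column
        top, second = vals[order[0]], vals[order[1]]
        tied = top == second
        if tied:
            # exact ties are resolved in favor of the earlier signature
            log.info(
                "cluster %s: tie between %s and %s; keeping %s",
                cluster_id, type_cols[order[0]], type_cols[order[1]],
                type_cols[order[0]],
            )
            scores.ties.append((cluster_id, type_cols[order[0]], type_cols[order[1]]))
        if top < 0 or (not tied and (top - second) < margin_min):
            labels[cluster_id] = NOT_IDENTIFIED
        else:
            labels[cluster_id] = type_cols[order[0]]
    return pd.Series(labels, name="cell_type")


def assign_cycle_phase(
    expr: ExpressionMatrix,
    sigs: SignatureSet,
    s_name: str = "S",
    g2m_name: str = "G2-M",
    scale: float = DEFAULT_SCALE,
) -> pd.Series:
    """Per-cell cycle phase: arg-max of the S / G2-M signature scores when
    positive, else "none"."""
    for name in (s_name, g2m_name):
        if name not in sigs.signatures:
            raise ValidationError(f"cycle signature {name!r} not provided")
    scores = score_signatures(
        expr, sigs.subset([s_name, g2m_name]), by="cell", scale=scale
    )
    s = scores.values[s_name].to_numpy()
    g2m = scores.values[g2m_name].to_numpy()
    phase = np.where(
        np.maximum(s, g2m) <= 0, "none", np.where(s >= g2m, s_name, g2m_name)
    )
    return pd.Series(phase, index=scores.values.index, name="cycle_phase")
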