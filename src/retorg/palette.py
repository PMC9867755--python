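"""Similarity coloring of enrichment results via their found entities.

Each enrichment result is encoded as a binary presence/absence row over
the union of found-entity genes; rows are embedded with PCA (20 PCs),
projected to 3D with a seeded t-SNE, and the three axes are min-max scaled
to RGB channels, so enrichments driven by overlapping gene sets receive
similar colors.  Identical found-entity sets are deduplicated before the
embedding, which guarantees they map to identical coordinates and hence
identical hex colors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from retorg.datatypes import ValidationError
from retorg.enrichment import EnrichmentResult

log = logging.getLogger(__name__)

#: Below this many distinct rows, a direct 3-PC projection replaces t-SNE
#: (t-SNE's repulsion dominates at tiny n and destroys distance structure).
TSNE_MIN_ROWS = 50


@dataclass
class FoundEntityMatrix:
    """Binary matrix: rows = enrichment results, columns = genes."""

    values: pd.DataFrame  # index = enrichment id, columns = gene symbols


@dataclass
class PaletteAssignment:
    coords: pd.DataFrame  # index = enrichment id, columns x, y, z
    hex_colors: pd.Series  # index = enrichment id


def enrichment_id(result: EnrichmentResult) -> str:
    return f"{result.query_name}::{result.set_name}"


def build_found_entity_matrix(results: list[EnrichmentResult]) -> FoundEntityMatrix:
    """Encode found-entity sets as a binary matrix with deterministic
    (sorted) row and column order."""
    if len(results) < 2:
        raise ValidationError("need at least two enrichment results")
    for r in results:
        if not r.found_entities:
            raise ValidationError(
                f"enrichment {enrichment_id(r)} has an empty found-entity set"
            )
    ids = sorted(enrichment_id(r) for r in results)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate enrichment ids")
    by_id = {enrichment_id(r): r for r in results}
    genes = sorted(set().union(*(r.found_entities for r in results)))
    col = {g: j for j, g in enumerate(genes)}
    mat = np.zeros((len(ids), len(genes)), dtype=np.int8)
    for i, rid in enumerate(ids):
        for g in by_id[rid].found_entities:
            mat[i, col[g]] = 1
    return FoundEntityMatrix(values=pd.DataFrame(mat, index=ids, columns=genes))


def pca_embed(matrix: np.ndarray | pd.DataFrame, n_pcs: int = 20) -> np.ndarray:
    """Column-centered PCA scores via SVD, components by decreasing
    variance, sign fixed so each component's largest-magnitude loading is
    positive.  ``n_pcs`` is capped at the matrix rank."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least two rows")
    centered = X - X.mean(axis=0)
    if not np.any(centered):
        raise ValidationError("matrix has zero variance")
    rank = np.linalg.matrix_rank(centered)
    if n_pcs > rank:
        log.warning("n_pcs reduced from %d to matrix rank %d", n_pcs, rank)
        n_pcs = rank
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| positive per component
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return scores


def embed_3d(
    pcs: np.ndarray,
    seed: int = 0,
    perplexity: float | None = None,
    n_iter: int = 1000,
) -> np.ndarray:
    """Seeded 3D embedding of the PC coordinates.

    Duplicate PC rows are collapsed before the embedding and re-expanded
    afterwards, so identical inputs are guaranteed coincident outputs.
    t-SNE is used when there are at least ``TSNE_MIN_ROWS`` distinct rows
    (the regime the method is designed for); below that the first three
    PCs are used directly, which preserves the distance structure exactly
    instead of exaggerating it.  ``perplexity`` defaults to
    min(30, (rows - 1) / 3) over the unique rows; an explicitly requested
    perplexity that is too large for the row count is an error.
    """
    pcs = np.asarray(pcs, dtype=float)
    uniq, inverse = np.unique(pcs, axis=0, return_inverse=True)
    n = uniq.shape[0]
    max_perp = (n - 1) / 3.0
    if perplexity is not None and perplexity >= max_perp:
        raise ValidationError(
            f"perplexity {perplexity} needs more than {int(3 * perplexity) + 1} "
            f"distinct rows (got {n})"
        )
    if perplexity is None:
        perplexity = min(30.0, max(0.5, max_perp * 0.999))
    if n < TSNE_MIN_ROWS:
        coords = np.zeros((n, 3))
        take = min(3, uniq.shape[1])
        coords[:, :take] = uniq[:, :take]
    else:
        tsne = TSNE(
            n_components=3,
            perplexity=perplexity,
            random_state=seed & 0x7FFFFFFF,
            init="pca" if uniq.shape[1] >= 3 else "random",
            max_iter=n_iter,
        )
        coords = tsne.fit_transform(uniq)
    return coords[inverse]


def nn_preservation(pcs: np.ndarray, coords3d: np.ndarray, k: int = 5) -> float:
    """Diagnostic: average fraction of each row's k nearest neighbors in PC
    space that are also among its k nearest neighbors in 3D."""
    from scipy.spatial import cKDTree

    pcs = np.asarray(pcs, float)
    coords3d = np.asarray(coords3d, float)
    n = pcs.shape[0]
    k = min(k, n - 1)
    if k < 1:
        return 1.0
    _, nn_a = cKDTree(pcs).query(pcs, k=k + 1)
    _, nn_b = cKDTree(coords3d).query(coords3d, k=k + 1)
    keep = 0.0
    for i in range(n):
        a = set(nn_a[i][nn_a[i] != i][:k])
        b = set(nn_b[i][nn_b[i] != i][:k])
        keep += len(a & b) / k
    return keep / n


def coords_to_hex(coords3d: np.ndarray) -> list[str]:
    """Min-max scale each axis to 0..255 (half-up rounding) and format as
    #RRGGBB.  With fewer than two distinct points everything is mid-gray."""
    coords = np.asarray(coords3d, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError("expected an (n, 3) coordinate array")
    if np.unique(coords, axis=0).shape[0] < 2:
        return ["#808080"] * coords.shape[0]
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    scaled = np.where(span > 0, (coords - lo) / np.where(span > 0, span, 1.0), 0.5)
    channels = np.floor(scaled * 255 + 0.5).astype(int)  # round half-up
    return ["#%02X%02X%02X" % tuple(row) for row in channels]


def color_enrichments(
    results: list[EnrichmentResult],
    n_pcs: int = 20,
    seed: int = 0,
    perplexity: float | None = None,
    n_iter: int = 1000,
) -> PaletteAssignment:
    """Full pipeline: found-entity matrix -> PCA -> 3D t-SNE -> hex colors."""
    fem = build_found_entity_matrix(results)
    pcs = pca_embed(fem.values, n_pcs=n_pcs)
    coords = embed_3d(pcs, seed=seed, perplexity=perplexity, n_iter=n_iter)
    hexes = coords_to_hex(coords)
    frame = pd.DataFrame(coords, index=fem.values.index, columns=["x", "y", "z"])
    return PaletteAssignment(
        coords=frame, hex_colors=pd.Series(hexes, index=fem.values.index, name="hex")
    )
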