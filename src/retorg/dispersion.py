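"""Dispersion statistics on the 2D embedding.

Two complementary measures quantify how tightly each condition's cells
follow the developmental manifold:

* **Trajectory width** — the mean Euclidean distance from a sampled cell to
  its n nearest neighbors (n = 1..n_max) among cells of the same condition,
  after equalizing per-stage cell numbers between conditions by
  down-sampling.  Wider curves mean more dispersed trajectories.

* **Within-stage diversity** — the fraction of randomly sampled same-stage,
  same-condition cell pairs that share a cell-type label (a "1 - entropy"
  statistic whose large-sample expectation is the Simpson index of the
  stage's type composition).  Lower values mean more cell-type diversity
  within a stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from retorg.config import PipelineConfig
from retorg.datatypes import CONDITIONS, STAGES, CellTable, ValidationError

log = logging.getLogger(__name__)


@dataclass
class WidthCurveSet:
    """Per-condition width curves with a replicate envelope.

    ``curves[condition]`` has shape (replicates, n_max): mean n-NN distance
    per replicate.  ``mean``/``lo``/``hi`` aggregate across replicates
    (pointwise average, minimum and maximum).
    """

    curves: dict[str, np.ndarray]
    n_cells: int
    n_max: int
    replicates: int
    seed: int

    def mean(self, condition: str) -> np.ndarray:
        return self.curves[condition].mean(axis=0)

    def lo(self, condition: str) -> np.ndarray:
        return self.curves[condition].min(axis=0)

    def hi(self, condition: str) -> np.ndarray:
        return self.curves[condition].max(axis=0)


@dataclass
class DiversityEstimate:
    """Per condition x stage same-type pair-fraction samples.

    ``samples[(condition, stage)]`` is one value per down-sampling
    replicate: the fraction of sampled within-stage cell pairs whose two
    cells share a cell-type label.
    """

    samples: dict[tuple[str, str], np.ndarray]
    pairs: int
    replicates: int
    seed: int

    def mean(self, condition: str, stage: str) -> float:
        return float(self.samples[(condition, stage)].mean())


def euclid_2d(p1, p2) -> float:
    """Euclidean distance between two 2D points."""
    (x1, y1), (x2, y2) = p1, p2
    return float(np.hypot(x1 - x2, y1 - y2))


def knn_mean_distance(
    points: np.ndarray, query_indices: np.ndarray, n_max: int
) -> np.ndarray:
    """Mean distance from each query point to its n nearest neighbors.

    Returns an array of shape (len(query_indices), n_max) whose [i, n-1]
    entry is the mean of the distances from query i to its n closest other
    points (self excluded by index, so coincident points still count as
    neighbors).
    """
    points = np.asarray(points, dtype=float)
    query_indices = np.asarray(query_indices, dtype=int)
    n_points = points.shape[0]
    if n_max >= n_points:
        raise ValidationError(
            f"n_max={n_max} requires more than {n_points} points in the pool"
        )
    tree = cKDTree(points)
    dist, idx = tree.query(points[query_indices], k=n_max + 1)
    # drop each query's own entry; with ties at distance 0 the self index
    # may fall anywhere in the tie block, so locate it explicitly
    out = np.empty((len(query_indices), n_max))
    for row, qi in enumerate(query_indices):
        self_pos = np.nonzero(idx[row] == qi)[0]
        drop = self_pos[0] if self_pos.size else n_max
        d = np.delete(dist[row], drop)
        out[row] = np.cumsum(d) / np.arange(1, n_max + 1)
    return out


def _balanced_stage_pools(
    table: CellTable, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Equalize per-stage cell numbers between conditions by down-sampling
    the more populated condition without replacement.  Returns per-condition
    arrays of cell indices."""
    pools: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    for stage in STAGES:
        per_cond = {}
        for cond in CONDITIONS:
            per_cond[cond] = np.flatnonzero(
                (table.stage == stage) & (table.condition == cond)
            )
        sizes = {c: len(ix) for c, ix in per_cond.items()}
        if min(sizes.values()) == 0:
            continue
        target = min(sizes.values())
        for cond, ix in per_cond.items():
            if len(ix) > target:
                ix = rng.choice(ix, size=target, replace=False)
            pools[cond].append(np.sort(ix))
    return {c: np.concatenate(v) if v else np.empty(0, int) for c, v in pools.items()}


def trajectory_width(table: CellTable, cfg: PipelineConfig) -> WidthCurveSet:
    """Compute per-condition trajectory-width curves.

    Per replicate: (1) within each stage, down-sample the more populated
    condition to equalize counts; (2) sample ``n_cells_width`` cells per
    condition from its balanced pool; (3) for each sampled cell, average
    the distances to its n nearest neighbors within the balanced pool of
    its own condition, n = 1..n_max; (4) average over sampled cells.  The
    envelope is the pointwise min/max across replicates.
    """
    seed = cfg.rng_seed if cfg.rng_seed is not None else 0
    rng = np.random.default_rng(seed)
    for cond in CONDITIONS:
        if not (table.condition == cond).any():
            raise ValidationError(f"condition {cond!r} absent from the data")
    n_max = cfg.n_max
    curves = {c: np.empty((cfg.width_replicates, 0)) for c in CONDITIONS}
    per_rep = {c: [] for c in CONDITIONS}
    for _rep in range(cfg.width_replicates):
        pools = _balanced_stage_pools(table, rng)
        for cond in CONDITIONS:
            pool = pools[cond]
            if len(pool) < 2:
                raise ValidationError(
                    f"condition {cond!r}: balanced pool too small ({len(pool)} cells)"
                )
            eff_n_max = n_max
            if eff_n_max >= len(pool):
                eff_n_max = len(pool) - 1
                log.warning(
                    "n_max capped at %d (pool of %d cells)", eff_n_max, len(pool)
                )
            n_query = min(cfg.n_cells_width, len(pool))
            if n_query < cfg.n_cells_width:
                log.warning(
                    "condition %s: only %d cells available for the %d-cell sample",
                    cond, n_query, cfg.n_cells_width,
                )
            query_local = rng.choice(len(pool), size=n_query, replace=False)
            per_query = knn_mean_distance(
                table.embedding[pool], query_local, eff_n_max
            )
            curve = np.full(n_max, np.nan)
            curve[:eff_n_max] = per_query.mean(axis=0)
            per_rep[cond].append(curve)
    for cond in CONDITIONS:
        curves[cond] = np.vstack(per_rep[cond])
    return WidthCurveSet(
        curves=curves,
        n_cells=cfg.n_cells_width,
        n_max=n_max,
        replicates=cfg.width_replicates,
        seed=seed,
    )


def stage_diversity(table: CellTable, cfg: PipelineConfig) -> DiversityEstimate:
    """Within-stage cell-type diversity by pair resampling.

    Per down-sampling replicate and per condition x stage: draw
    ``entropy_pairs`` unordered pairs of two distinct cells uniformly (with
    replacement across pairs) and record the fraction of pairs whose cells
    share a cell-type label.  Down-sampling equalizes per-stage cell counts
    between conditions before each replicate.
    """
    seed = cfg.rng_seed if cfg.rng_seed is not None else 0
    rng = np.random.default_rng(seed)
    for stage in STAGES:
        for cond in CONDITIONS:
            n = int(((table.stage == stage) & (table.condition == cond)).sum())
            if 0 < n < 2:
                raise ValidationError(
                    f"condition {cond!r} stage {stage!r} has {n} cell(s); need >= 2"
                )
    samples: dict[tuple[str, str], list[float]] = {}
    for _rep in range(cfg.entropy_replicates):
        pools = _balanced_stage_pools(table, rng)
        for cond in CONDITIONS:
            pool = pools[cond]
            stages = table.stage[pool]
            types = table.cell_type[pool]
            for stage in STAGES:
                members = np.flatnonzero(stages == stage)
                if len(members) < 2:
                    continue
                labels = types[members]
                first = rng.integers(0, len(members), size=cfg.entropy_pairs)
                # second cell drawn among the remaining ones (distinct pair)
                shift = rng.integers(1, len(members), size=cfg.entropy_pairs)
                second = (first + shift) % len(members)
                frac = float(np.mean(labels[first] == labels[second]))
                samples.setdefault((cond, stage), []).append(frac)
    return DiversityEstimate(
        samples={k: np.asarray(v) for k, v in samples.items()},
        pairs=cfg.entropy_pairs,
        replicates=cfg.entropy_replicates,
        seed=seed,
    )


def simpson_same_type_probability(composition: dict[str, int]) -> float:
    """Exact probability that two distinct cells drawn without replacement
    from ``composition`` share a type: sum n_i (n_i - 1) / (N (N - 1))."""
    counts = np.array(list(composition.values()), dtype=float)
    total = counts.sum()
    if total < 2:
        raise ValidationError("need at least two cells")
    return float((counts * (counts - 1)).sum() / (total * (total - 1)))
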