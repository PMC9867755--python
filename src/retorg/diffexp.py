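"""Differential expression between cell types and between conditions.

All tests operate on fraction-of-UMI expression and use the two-sided
Wilcoxon rank-sum test.  "Cell-type-specifying" genes are over-expressed
in one type versus all others (ln-fold-change >= 0.25, p <= 0.001);
condition contrasts (native vs organoid within a type) are reported per
direction at BH q <= 0.01.  Log fold changes are natural logs of mean
expression ratios with a small pseudocount.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from retorg.config import PipelineConfig
from retorg.datatypes import CONDITIONS, ExpressionMatrix, GeneList, ValidationError

log = logging.getLogger(__name__)

TYPE_VS_REST = "type_vs_rest"
NATIVE_GT_ORGANOID = "native_gt_organoid"
ORGANOID_GT_NATIVE = "organoid_gt_native"


@dataclass
class DERecord:
    gene: str
    contrast: str
    cell_type: str
    log_fold_change: float
    p_value: float
    q_value: float = float("nan")

    @property
    def direction(self) -> str:
        return "up" if self.log_fold_change > 0 else "down"


@dataclass
class TFAnnotation:
    gene: str
    is_tf: bool
    top_type: str
    specificity_fold: float
    flagged: bool


def rank_sum_test(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration of all group assignments when both groups have at
    most 10 observations (valid with ties, using midranks); otherwise the
    normal approximation with tie correction.  Returns 1 when every value
    in both groups is identical.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if a.size <= 10 and b.size <= 10:
        return _exact_rank_sum(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _exact_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Enumerate all C(n+m, n) assignments of the pooled midranks.

    The null distribution of the rank sum is symmetric about its mean even
    under ties (reversing the rank order maps each assignment to a mirror
    one), so the two-sided p is the probability of a deviation from the
    mean at least as large as observed.
    """
    n, m = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    observed = ranks[:n].sum()
    center = n * (ranks.sum()) / (n + m)
    dev = abs(observed - center)
    count = 0
    total = 0
    for combo in combinations(range(n + m), n):
        total += 1
        if abs(ranks[list(combo)].sum() - center) >= dev - 1e-12:
            count += 1
    return count / total


def _ranksum_pvalues_matrix(group: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p per gene (columns).  Asymptotic with
    tie correction; all-tied columns get p = 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(
            group, rest, alternative="two-sided", method="asymptotic", axis=0
        )
        p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _usable(expr: ExpressionMatrix) -> np.ndarray:
    return ~expr.zero_count_cells


def cell_type_specifying(
    expr: ExpressionMatrix,
    cell_type: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> list[DERecord]:
    """Genes over-expressed in one cell type versus all other cells.

    For each type with at least 3 cells, every gene is tested type vs
    rest; records are kept when ln-fold-change >= ``logfc_min`` and
    p <= ``p_max``.
    """
    cfg = cfg or PipelineConfig()
    cell_type = np.asarray(cell_type)
    usable = _usable(expr)
    types = [t for t in np.unique(cell_type) if t != "NI"]
    if len(types) < 2:
        raise ValidationError("need at least two cell types")
    records: list[DERecord] = []
    values = expr.values
    pc = cfg.pseudocount
    for ctype in types:
        in_type = usable & (cell_type == ctype)
        rest = usable & (cell_type != ctype)
        if in_type.sum() < 3:
            log.warning("cell type %s has <3 cells; skipped", ctype)
            continue
        mean_t = values[in_type].mean(axis=0)
        mean_r = values[rest].mean(axis=0)
        logfc = np.log((mean_t + pc) / (mean_r + pc))
        candidate = logfc >= cfg.logfc_min
        if not candidate.any():
            continue
        p = np.ones(values.shape[1])
        p[candidate] = _ranksum_pvalues_matrix(
            values[in_type][:, candidate], values[rest][:, candidate]
        )
        keep = candidate & (p <= cfg.p_max)
        for gi in np.flatnonzero(keep):
            records.append(
                DERecord(
                    gene=expr.gene_ids[gi],
                    contrast=TYPE_VS_REST,
                    cell_type=str(ctype),
                    log_fold_change=float(logfc[gi]),
                    p_value=float(p[gi]),
                )
            )
    return records


def condition_contrast(
    expr: ExpressionMatrix,
    cell_type: np.ndarray,
    condition: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> dict[str, list[DERecord]]:
    """Native-vs-organoid differential expression within each cell type.

    Per type, every gene gets a two-sided rank-sum p; genes are split by
    the sign of ln(native mean / organoid mean) and BH q-values are
    computed within each (type, direction) family.  Records at
    q <= ``q_max`` are returned keyed by contrast name.
    """
    cfg = cfg or PipelineConfig()
    cell_type = np.asarray(cell_type)
    condition = np.asarray(condition)
    usable = _usable(expr)
    out: dict[str, list[DERecord]] = {NATIVE_GT_ORGANOID: [], ORGANOID_GT_NATIVE: []}
    values = expr.values
    pc = cfg.pseudocount
    for ctype in (t for t in np.unique(cell_type) if t != "NI"):
        in_type = usable & (cell_type == ctype)
        nat = in_type & (condition == CONDITIONS[0])
        org = in_type & (condition == CONDITIONS[1])
        if nat.sum() < 3 or org.sum() < 3:
            log.warning(
                "cell type %s present in only one condition (or <3 cells); skipped",
                ctype,
            )
            continue
        mean_n = values[nat].mean(axis=0)
        mean_o = values[org].mean(axis=0)
        logfc = np.log((mean_n + pc) / (mean_o + pc))
        p = _ranksum_pvalues_matrix(values[nat], values[org])
        for contrast, mask in (
            (NATIVE_GT_ORGANOID, logfc > 0),
            (ORGANOID_GT_NATIVE, logfc < 0),
        ):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            q = adjust_fdr(p[idx])
            for gi, qv in zip(idx, q):
                if qv <= cfg.q_max:
                    out[contrast].append(
                        DERecord(
                            gene=expr.gene_ids[gi],
                            contrast=contrast,
                            cell_type=str(ctype),
                            log_fold_change=float(logfc[gi]),
                            p_value=float(p[gi]),
                            q_value=float(qv),
                        )
                    )
    return out


def tf_specificity(
    expr: ExpressionMatrix,
    cell_type: np.ndarray,
    tf_list: GeneList,
    specifying_genes: set[str] | None = None,
    fold: float = 1.5,
    pseudocount: float = 1e-9,
) -> list[TFAnnotation]:
    """Per-TF cell-type specificity fold.

    For each TF (optionally restricted to the cell-type-specifying genes),
    the fold is the highest per-type mean expression divided by the
    second-highest; TFs with fold >= ``fold`` are flagged as
    single-type-specific.
    """
    if not tf_list.genes:
        raise ValidationError("empty TF list")
    cell_type = np.asarray(cell_type)
    usable = _usable(expr)
    types = [t for t in np.unique(cell_type) if t != "NI"]
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    candidates = sorted(
        g
        for g in tf_list.genes
        if g in gene_pos and (specifying_genes is None or g in specifying_genes)
    )
    type_means = np.vstack(
        [expr.values[usable & (cell_type == t)].mean(axis=0) for t in types]
    )
    annotations = []
    for gene in candidates:
        means = type_means[:, gene_pos[gene]]
        order = np.argsort(means)[::-1]
        top, second = means[order[0]], means[order[1]]
        spec = (top + pseudocount) / (second + pseudocount)
        annotations.append(
            TFAnnotation(
                gene=gene,
                is_tf=True,
                top_type=str(types[order[0]]),
                specificity_fold=float(spec),
                flagged=bool(spec >= fold),
            )
        )
    return annotations


def bootstrap_mean_ci(
    values,
    n_boot: int = 1000,
    level: float = 0.99,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the mean: (mean, lo, hi)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("need at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot_means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha])
    return float(x.mean()), float(lo), float(hi)
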