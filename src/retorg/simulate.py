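"""Synthetic two-condition, four-stage retinal scRNA-seq generator.

Cells are placed on a branching 2D trajectory tree whose branches mirror
the canonical retinal lineages (NE -> RPE, NE -> ERPC -> NRPC -> RGC,
LRPC -> NRPC -> AC, LRPC -> PRP -> C/R/BP, LRPC -> MC, plus a detached HC
branch).  Each branch carries one cell type and a pseudotime interval;
stages I-IV partition pseudotime into four windows.  Native and organoid
cells share the tree but differ in three ground-truth ways that the
analysis statistics are designed to detect:

* isotropic Gaussian jitter around the branch is wider for organoid cells
  (``sigma_organoid`` > ``sigma_native``), widening their trajectories;
* an organoid cell's pseudotime is drawn from an adjacent stage's window
  with probability ``mixing_excess_organoid`` while keeping its stage
  label, increasing within-stage cell-type diversity;
* a configurable per-type abundance multiplier (by default a photoreceptor
  precursor excess at stages II-III) skews organoid type composition.

UMI counts follow a negative-binomial model with log-normal library sizes.
Marker genes of a cell's type have their mean multiplied by
exp(marker_log_fold); planted perturbed genes are multiplied by
exp(+/- perturb_log_fold) in organoid cells of the targeted type only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from retorg.datatypes import (
    CELL_TYPES,
    CONDITIONS,
    STAGES,
    CellTable,
    ValidationError,
)


@dataclass(frozen=True)
class Branch:
    name: str
    cell_type: str
    start: tuple[float, float]
    end: tuple[float, float]
    t0: float
    t1: float
    parent: str | None = None


#: Default trajectory tree.  Geometry is schematic; what matters for the
#: statistics is the branch topology, the one-type-per-branch labelling and
#: the pseudotime intervals.  The HC branch is deliberately detached from
#: the rest of the manifold, as observed in real retinal embeddings.
DEFAULT_TREE: tuple[Branch, ...] = (
    Branch("NE", "NE", (0.0, 0.0), (1.0, 0.0), 0.0, 0.8),
    Branch("RPE", "RPE", (1.0, 0.0), (1.8, 0.8), 0.9, 2.0, parent="NE"),
    Branch("ERPC", "ERPC", (1.0, 0.0), (2.0, -0.6), 0.6, 1.5, parent="NE"),
    Branch("NRPC", "NRPC", (2.0, -0.6), (3.0, -0.2), 1.5, 2.1, parent="ERPC"),
    Branch("RGC", "RGC", (3.0, -0.2), (4.0, 0.2), 1.0, 3.0, parent="NRPC"),
    Branch("LRPC", "LRPC", (2.0, -0.6), (2.8, -1.4), 1.2, 2.3, parent="ERPC"),
    Branch("HC", "HC", (0.5, -2.5), (1.3, -2.9), 2.0, 3.1),
    Branch("AC", "AC", (2.8, -1.4), (3.6, -1.0), 2.1, 3.1, parent="LRPC"),
    Branch("PRP", "PRP", (2.8, -1.4), (3.6, -2.2), 1.9, 3.2, parent="LRPC"),
    Branch("C", "C", (3.6, -2.2), (4.4, -1.8), 3.0, 4.1, parent="PRP"),
    Branch("R", "R", (3.6, -2.2), (4.4, -2.6), 3.1, 4.0, parent="PRP"),
    Branch("BP", "BP", (3.6, -2.2), (3.9, -3.0), 3.0, 3.9, parent="PRP"),
    Branch("MC", "MC", (2.8, -1.4), (2.6, -2.4), 3.0, 4.1, parent="LRPC"),
)

DEFAULT_STAGE_WINDOWS: dict[str, tuple[float, float]] = {
    "I": (0.0, 1.0),
    "II": (1.0, 2.0),
    "III": (2.0, 3.0),
    "IV": (3.0, 4.0),
}

#: Organoid photoreceptor-precursor excess: strong premature emergence at
#: stage II (PRP barely exists natively there) and a mild surplus at III.
DEFAULT_ABUNDANCE_MULTIPLIERS: dict[tuple[str, str, str], float] = {
    ("organoid", "II", "PRP"): 3.0,
    ("organoid", "III", "PRP"): 1.2,
}


@dataclass
class SynthConfig:
    branch_tree: tuple[Branch, ...] = DEFAULT_TREE
    stage_window: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_WINDOWS)
    )
    sigma_native: float = 0.3
    sigma_organoid: float = 0.6
    cells_per_condition_stage: int = 500
    n_genes: int = 600
    markers_per_type: int = 10
    marker_log_fold: float = 1.5
    nb_dispersion: float = 0.3
    n_tf_genes: int = 60
    perturbed_tf_fraction: float = 0.2
    perturb_log_fold: float = 1.0
    mixing_excess_organoid: float = 0.15
    abundance_multipliers: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ABUNDANCE_MULTIPLIERS)
    )
    library_size_log_mean: float = 7.6  # ~2000 UMI per cell
    library_size_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.branch_tree:
            raise ValidationError("branch tree is empty")
        if self.sigma_native < 0 or self.sigma_organoid < 0:
            raise ValidationError("jitter sigmas must be non-negative")
        for name in ("perturbed_tf_fraction", "mixing_excess_organoid"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.cells_per_condition_stage < 1 or self.n_genes < 1:
            raise ValidationError("cell and gene counts must be positive")
        names = {b.name for b in self.branch_tree}
        if len(names) != len(self.branch_tree):
            raise ValidationError("branch names must be unique")
        for b in self.branch_tree:
            if b.parent is not None and b.parent not in names:
                raise ValidationError(f"branch {b.name}: unknown parent {b.parent}")
            if b.t1 <= b.t0:
                raise ValidationError(f"branch {b.name}: empty pseudotime interval")


@dataclass
class GroundTruth:
    """Everything the generator knows and the analysis must recover."""

    pseudotime: np.ndarray
    branch: np.ndarray
    cell_type: np.ndarray
    marker_map: dict[str, str]  # gene -> cell type
    perturbation_map: dict[str, tuple[str, str, float]]  # gene -> (type, dir, lfc)
    tf_genes: list[str]

    def markers_of(self, cell_type: str) -> list[str]:
        return sorted(g for g, t in self.marker_map.items() if t == cell_type)


def stage_rng(seed: int, name: str) -> np.random.Generator:
    """A named child generator, so pipeline stages can be re-run
    independently while all randomness still flows from one seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _branch_weights(
    cfg: SynthConfig, condition: str, stage: str, window: tuple[float, float]
) -> tuple[list[Branch], np.ndarray]:
    lo, hi = window
    branches, weights = [], []
    for b in cfg.branch_tree:
        overlap = min(hi, b.t1) - max(lo, b.t0)
        if overlap <= 0:
            continue
        mult = cfg.abundance_multipliers.get((condition, stage, b.cell_type), 1.0)
        branches.append(b)
        weights.append(overlap * mult)
    if not branches:
        raise ValidationError(f"no branch overlaps stage {stage} window {window}")
    w = np.asarray(weights, dtype=float)
    return branches, w / w.sum()


def generate_manifold(cfg: SynthConfig) -> tuple[CellTable, GroundTruth]:
    """Place cells on the trajectory tree.

    Returns a CellTable whose count matrix is empty (0 genes) but whose
    embedding, condition, stage, cluster and cell_type columns are filled,
    plus the per-cell ground truth.  Cell counts per condition x stage are
    exactly ``cells_per_condition_stage``.
    """
    rng = stage_rng(cfg.seed, "manifold")
    sigma = {"native": cfg.sigma_native, "organoid": cfg.sigma_organoid}
    stage_list = [s for s in STAGES if s in cfg.stage_window]
    rows = []
    for condition in CONDITIONS:
        for si, stage in enumerate(stage_list):
            for _ in range(cfg.cells_per_condition_stage):
                draw_stage = stage
                if (
                    condition == "organoid"
                    and cfg.mixing_excess_organoid > 0
                    and rng.random() < cfg.mixing_excess_organoid
                ):
                    # pseudotime drawn one stage off; the stage label stays
                    adjacent = [
                        stage_list[j]
                        for j in (si - 1, si + 1)
                        if 0 <= j < len(stage_list)
                    ]
                    draw_stage = adjacent[rng.integers(len(adjacent))]
                window = cfg.stage_window[draw_stage]
                branches, probs = _branch_weights(cfg, condition, draw_stage, window)
                b = branches[rng.choice(len(branches), p=probs)]
                lo = max(window[0], b.t0)
                hi = min(window[1], b.t1)
                t = rng.uniform(lo, hi)
                frac = (t - b.t0) / (b.t1 - b.t0)
                pos = (1 - frac) * np.asarray(b.start) + frac * np.asarray(b.end)
                pos = pos + rng.normal(0.0, sigma[condition], size=2)
                rows.append((condition, stage, b, t, frac, pos))
    n = len(rows)
    branch_index = {b.name: i for i, b in enumerate(cfg.branch_tree)}
    table = CellTable(
        counts=np.zeros((n, 0), dtype=np.int64),
        gene_ids=[],
        cell_ids=[f"cell{i:05d}" for i in range(n)],
        condition=np.array([r[0] for r in rows], dtype=object),
        stage=np.array([r[1] for r in rows], dtype=object),
        # two clusters per branch (proximal/distal half) stand in for the
        # fine-grained k-means clustering of real pipelines
        cluster=np.array(
            [branch_index[r[2].name] * 2 + (r[4] > 0.5) for r in rows],
            dtype=np.int64,
        ),
        cell_type=np.array([r[2].cell_type for r in rows], dtype=object),
        embedding=np.vstack([r[5] for r in rows]),
    )
    truth = GroundTruth(
        pseudotime=np.array([r[3] for r in rows]),
        branch=np.array([r[2].name for r in rows], dtype=object),
        cell_type=table.cell_type.copy(),
        marker_map={},
        perturbation_map={},
        tf_genes=[],
    )
    return table, truth


def _plan_genes(cfg: SynthConfig, rng: np.random.Generator):
    """Choose gene names, baseline abundances, marker and TF assignments."""
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    types = [t for t in CELL_TYPES if any(b.cell_type == t for b in cfg.branch_tree)]
    n_markers = cfg.markers_per_type * len(types)
    if n_markers + cfg.n_tf_genes > cfg.n_genes:
        raise ValidationError("n_genes too small for the requested markers and TFs")
    marker_map: dict[str, str] = {}
    pos = 0
    for t in types:
        for _ in range(cfg.markers_per_type):
            marker_map[gene_ids[pos]] = t
            pos += 1
    # TFs: two markers per type plus additional non-marker genes
    tf_genes: list[str] = []
    for t in types:
        tf_genes.extend(gene_ids[types.index(t) * cfg.markers_per_type : types.index(t) * cfg.markers_per_type + 2])
    extra = cfg.n_tf_genes - len(tf_genes)
    if extra > 0:
        tf_genes.extend(gene_ids[n_markers : n_markers + extra])
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    # planted genes get at-least-median abundance so their effects are
    # observable at the simulated sequencing depth
    floor = float(np.median(baseline))
    planted = set(marker_map) | set(tf_genes)
    for gi, g in enumerate(gene_ids):
        if g in planted and baseline[gi] < floor:
            baseline[gi] = floor
    n_perturbed = int(round(cfg.perturbed_tf_fraction * len(tf_genes)))
    perturbed = sorted(rng.choice(tf_genes, size=n_perturbed, replace=False))
    perturbation_map = {}
    for g in perturbed:
        target = marker_map.get(g) or types[rng.integers(len(types))]
        direction = "up" if rng.random() < 0.5 else "down"
        perturbation_map[g] = (target, direction, cfg.perturb_log_fold)
    return gene_ids, baseline, marker_map, perturbation_map, sorted(tf_genes)


def generate_counts(
    cells: CellTable, cfg: SynthConfig, truth: GroundTruth
) -> tuple[CellTable, GroundTruth]:
    """Fill in negative-binomial UMI counts for a generated manifold.

    The per-cell, per-gene mean is ``library_size x relative_abundance``
    modulated by the planted marker and perturbation multipliers; counts
    are NB with variance m + nb_dispersion * m^2.
    """
    rng = stage_rng(cfg.seed, "counts")
    gene_ids, baseline, marker_map, perturbation_map, tf_genes = _plan_genes(cfg, rng)
    n_cells = cells.n_cells
    rel = baseline / baseline.sum()
    lib = rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd, n_cells)
    mean = lib[:, None] * rel[None, :]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    if cfg.marker_log_fold != 0:
        mult = np.exp(cfg.marker_log_fold)
        for gene, ctype in marker_map.items():
            mean[cells.cell_type == ctype, gene_pos[gene]] *= mult
    for gene, (ctype, direction, lfc) in perturbation_map.items():
        if lfc == 0:
            continue
        factor = np.exp(lfc if direction == "up" else -lfc)
        mask = (cells.cell_type == ctype) & (cells.condition == "organoid")
        mean[mask, gene_pos[gene]] *= factor
    size = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mean))
    table = CellTable(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        cell_ids=list(cells.cell_ids),
        condition=cells.condition,
        stage=cells.stage,
        cluster=cells.cluster,
        cell_type=cells.cell_type,
        embedding=cells.embedding,
    )
    truth.marker_map = marker_map
    truth.perturbation_map = perturbation_map
    truth.tf_genes = tf_genes
    return table, truth


def generate_dataset(cfg: SynthConfig | None = None) -> tuple[CellTable, GroundTruth]:
    """Manifold plus counts in one call."""
    cfg = cfg or SynthConfig()
    cells, truth = generate_manifold(cfg)
    return generate_counts(cells, cfg, truth)
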