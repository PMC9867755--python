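"""Protocol parameters and YAML configuration.

Defaults follow the published comparison protocol: trajectory-width curves
are computed from 500 sampled cells per condition over n = 1..50 nearest
neighbors with 5 replicates; within-stage diversity uses 1000 sampled cell
pairs per down-sampling replicate, 100 replicates; differential expression
uses ln-fold-change >= 0.25 with p <= 0.001 for cell-type-specifying genes
and BH q <= 0.01 for the condition contrasts; transcription-factor
specificity uses a 1.5x fold rule; expression-profile similarity counts
genes with Pearson r > 0.60; bootstrap CIs use 1000 resamples at the 99%
level; the found-entity embedding keeps 20 principal components.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from retorg.datatypes import ValidationError


@dataclass
class PipelineConfig:
    """All protocol parameters with their default values."""

    # trajectory width
    n_cells_width: int = 500
    n_max: int = 50
    width_replicates: int = 5
    # within-stage diversity
    entropy_pairs: int = 1000
    entropy_replicates: int = 100
    # differential expression
    logfc_min: float = 0.25
    p_max: float = 0.001
    q_max: float = 0.01
    pseudocount: float = 1e-9
    # TF specificity and profile correlation
    tf_fold: float = 1.5
    r_threshold: float = 0.60
    # bootstrap CIs
    bootstrap_n: int = 1000
    ci_level: float = 0.99
    # found-entity embedding
    n_pcs: int = 20
    enrich_keep_p: float = 0.01
    tsne_perplexity: float = 30.0
    tsne_iterations: int = 1000
    # global
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_cells_width", "n_max", "width_replicates", "entropy_pairs",
            "entropy_replicates", "bootstrap_n", "n_pcs", "tsne_iterations",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        for name in ("p_max", "q_max", "ci_level", "enrich_keep_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.logfc_min < 0:
            raise ValidationError("logfc_min must be non-negative")
        if self.tf_fold < 1:
            raise ValidationError("tf_fold must be >= 1")
        if not -1 <= self.r_threshold <= 1:
            raise ValidationError("r_threshold must lie in [-1, 1]")
        if self.tsne_perplexity <= 0:
            raise ValidationError("tsne_perplexity must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """A full pipeline run: parameters plus input locations.

    Either ``synthetic`` holds generator settings (see
    :class:`retorg.simulate.SynthConfig`) or the four ``*_path`` fields
    point at an on-disk MTX + TSV bundle.  ``rng_seed`` is mandatory so
    that every stochastic stage is reproducible.
    """

    params: PipelineConfig = field(default_factory=PipelineConfig)
    synthetic: dict | None = None
    matrix_path: str | None = None
    genes_path: str | None = None
    barcodes_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    tf_list_path: str | None = None
    disease_list_path: str | None = None
    outdir: str = "retorg_out"

    def __post_init__(self) -> None:
        if self.params.rng_seed is None:
            raise ValidationError("config must set rng_seed")
        if self.synthetic is None and self.matrix_path is None:
            raise ValidationError(
                "config needs either a synthetic: block or input paths"
            )


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    params = PipelineConfig(**raw.pop("params", {}))
    if "rng_seed" in raw:
        params.rng_seed = int(raw.pop("rng_seed"))
    return RunConfig(params=params, **raw)
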