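"""End-to-end pipeline: chain every analysis stage and write a report tree.

Stages (in order): annotate, width, entropy, de, enrich, palette,
correlate.  A run starts either from an on-disk MTX bundle or from the
synthetic generator (``synthetic:`` block in the config).  All stochastic
stages derive their generators from the single configured seed, so a rerun
with the same config reproduces every output byte for byte.  The manifest
records the seed, the parameters and every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from retorg import diffexp, dispersion, enrichment, io, palette, profiles, scoring
from retorg.config import PipelineConfig, RunConfig, load_config
from retorg.datatypes import CellTable, GeneList, normalize_fraction_umi
from retorg.enrichment import GeneSetCollection
from retorg.simulate import GroundTruth, SynthConfig, generate_dataset

log = logging.getLogger(__name__)

STAGES_IN_ORDER = (
    "annotate", "width", "entropy", "de", "enrich", "palette", "correlate",
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Holds the dataset and intermediate results while stages execute."""

    def __init__(self, run_cfg: RunConfig):
        self.cfg = run_cfg
        self.params: PipelineConfig = run_cfg.params
        self.outdir = Path(run_cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "seed": self.params.rng_seed,
            "params": self.params.to_dict(),
            "stages": {},
        }
        self.table: CellTable | None = None
        self.truth: GroundTruth | None = None
        self.signatures: scoring.SignatureSet | None = None
        self.pathways: GeneSetCollection | None = None
        self.tf_list: GeneList | None = None
        self.specifying: list[diffexp.DERecord] = []
        self.enrichments: list[enrichment.EnrichmentResult] = []

    # ------------------------------------------------------------------ input

    def load_data(self) -> CellTable:
        if self.table is not None:
            return self.table
        if self.cfg.synthetic is not None:
            synth = SynthConfig(seed=self.params.rng_seed, **self.cfg.synthetic)
            self.table, self.truth = generate_dataset(synth)
            paths = io.write_cell_table(self.table, self.outdir / "dataset")
            gt = pd.DataFrame(
                {
                    "barcode": self.table.cell_ids,
                    "pseudotime": self.truth.pseudotime,
                    "branch": self.truth.branch,
                    "cell_type": self.truth.cell_type,
                }
            )
            gt_path = self.outdir / "dataset" / "ground_truth.tsv"
            gt.to_csv(gt_path, sep="\t", index=False)
            self._record("simulate", dict(paths, ground_truth=gt_path))
            self.signatures = scoring.SignatureSet(
                {t: frozenset(self.truth.markers_of(t))
                 for t in sorted(set(self.truth.marker_map.values()))}
            )
            self.pathways = GeneSetCollection(
                sets={f"MARKERS_{t}": frozenset(self.truth.markers_of(t))
                      for t in sorted(set(self.truth.marker_map.values()))}
            )
            self.tf_list = GeneList("tf_catalogue", frozenset(self.truth.tf_genes))
        else:
            self.table = io.load_cell_table(
                self.cfg.matrix_path,
                self.cfg.genes_path,
                self.cfg.barcodes_path,
                self.cfg.metadata_path,
            )
            if self.cfg.gmt_path:
                self.pathways = io.read_gmt(self.cfg.gmt_path)
                self.signatures = scoring.SignatureSet(
                    dict(self.pathways.sets)
                )
            if self.cfg.tf_list_path:
                self.tf_list = io.read_gene_list(self.cfg.tf_list_path, "tf_catalogue")
        self.expr = normalize_fraction_umi(self.table)
        return self.table

    # ----------------------------------------------------------------- stages

    def _record(self, stage: str, paths: dict) -> None:
        self.manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in paths.items()
        }

    def stage_annotate(self) -> None:
        if self.signatures is None:
            log.warning("no signatures available; annotate stage skipped")
            self.manifest["stages"]["annotate"] = {}
            return
        scores = scoring.score_signatures(
            self.expr, self.signatures, by="cluster", cluster=self.table.cluster
        )
        assigned = scoring.assign_cell_types(scores)
        out_scores = self.outdir / "signature_scores.tsv"
        scores.values.round(6).rename_axis("cluster").to_csv(out_scores, sep="\t")
        frame = assigned.to_frame().rename_axis("cluster")
        type_cols = scores.values
        frame["top_score"] = type_cols.max(axis=1).round(6)
        second = type_cols.apply(lambda r: r.nlargest(2).iloc[-1], axis=1)
        frame["margin"] = (type_cols.max(axis=1) - second).round(6)
        out_types = self.outdir / "cluster_types.tsv"
        frame.to_csv(out_types, sep="\t")
        self.cluster_types = assigned
        self._record("annotate", {"scores": out_scores, "assignments": out_types})

    def stage_width(self) -> None:
        curves = dispersion.trajectory_width(self.table, self.params)
        rows = []
        for cond, mat in sorted(curves.curves.items()):
            for rep in range(mat.shape[0]):
                for n in range(mat.shape[1]):
                    rows.append((cond, rep + 1, n + 1, mat[rep, n]))
        frame = pd.DataFrame(
            rows, columns=["condition", "replicate", "n", "mean_distance"]
        )
        frame["seed"] = curves.seed
        out = self.outdir / "width_curves.tsv"
        frame.to_csv(out, sep="\t", index=False, float_format="%.9g")
        self.width_curves = curves
        self._record("width", {"curves": out})

    def stage_entropy(self) -> None:
        est = dispersion.stage_diversity(self.table, self.params)
        rows = []
        for (cond, stage), vals in sorted(est.samples.items()):
            for rep, v in enumerate(vals, start=1):
                rows.append((cond, stage, rep, v))
        frame = pd.DataFrame(rows, columns=["condition", "stage", "replicate", "value"])
        frame["seed"] = est.seed
        out = self.outdir / "diversity.tsv"
        frame.to_csv(out, sep="\t", index=False, float_format="%.9g")
        self.diversity = est
        self._record("entropy", {"diversity": out})

    def stage_de(self) -> None:
        native = self.table.condition == "native"
        expr_native = normalize_fraction_umi(self.table.subset_cells(native))
        self.specifying = diffexp.cell_type_specifying(
            expr_native, self.table.cell_type[native], self.params
        )
        contrasts = diffexp.condition_contrast(
            self.expr, self.table.cell_type, self.table.condition, self.params
        )
        records = self.specifying + contrasts[diffexp.NATIVE_GT_ORGANOID] + \
            contrasts[diffexp.ORGANOID_GT_NATIVE]
        frame = pd.DataFrame(
            [
                (r.gene, r.cell_type, r.contrast, r.log_fold_change, r.p_value,
                 r.q_value)
                for r in records
            ],
            columns=["gene", "cell_type", "contrast", "logFC", "p", "q"],
        ).sort_values(["contrast", "cell_type", "gene"], kind="stable")
        out_de = self.outdir / "differential_expression.tsv"
        frame.to_csv(out_de, sep="\t", index=False, float_format="%.6g")
        paths = {"de": out_de}
        if self.tf_list is not None:
            annotations = diffexp.tf_specificity(
                expr_native,
                self.table.cell_type[native],
                self.tf_list,
                specifying_genes={r.gene for r in self.specifying},
                fold=self.params.tf_fold,
            )
            tf_frame = pd.DataFrame(
                [
                    (a.gene, a.top_type, a.specificity_fold, a.flagged)
                    for a in annotations
                ],
                columns=["gene", "top_type", "specificity_fold", "flagged"],
            )
            out_tf = self.outdir / "tf_annotation.tsv"
            tf_frame.to_csv(out_tf, sep="\t", index=False, float_format="%.6g")
            paths["tf"] = out_tf
            self.tf_annotations = annotations
        self.contrasts = contrasts
        self._record("de", paths)

    def stage_enrich(self) -> None:
        if self.pathways is None:
            log.warning("no gene sets supplied; enrich stage skipped")
            self.manifest["stages"]["enrich"] = {}
            return
        universe = GeneList("universe", frozenset(self.table.gene_ids))
        self.enrichments = []
        per_type: dict[str, set[str]] = {}
        for r in self.specifying:
            per_type.setdefault(r.cell_type, set()).add(r.gene)
        for ctype in sorted(per_type):
            query = GeneList(f"specifying_{ctype}", frozenset(per_type[ctype]))
            self.enrichments.extend(
                enrichment.enrich_collection(
                    query, self.pathways, universe, keep_p=self.params.enrich_keep_p
                )
            )
        frame = pd.DataFrame(
            [
                (
                    r.query_name, r.set_name, r.universe_size, r.overlap,
                    r.p_value, r.q_value, ";".join(sorted(r.found_entities)),
                )
                for r in self.enrichments
            ],
            columns=["query", "set", "universe", "overlap", "p", "q",
                     "found_entities"],
        )
        out = self.outdir / "enrichment.tsv"
        frame.to_csv(out, sep="\t", index=False, float_format="%.6g")
        self._record("enrich", {"enrichment": out})

    def stage_palette(self) -> None:
        if len(self.enrichments) < 2:
            log.warning("fewer than two enrichments; palette stage skipped")
            self.manifest["stages"]["palette"] = {}
            return
        assignment = palette.color_enrichments(
            self.enrichments,
            n_pcs=self.params.n_pcs,
            seed=self.params.rng_seed,
            n_iter=self.params.tsne_iterations,
        )
        frame = assignment.coords.round(6).rename_axis("enrichment")
        frame["hex"] = assignment.hex_colors
        out = self.outdir / "palette.tsv"
        frame.to_csv(out, sep="\t")
        self._record("palette", {"palette": out})

    def stage_correlate(self) -> None:
        genes = GeneList("profiled", frozenset(
            g for r in self.specifying for g in [r.gene]
        )) if self.specifying else GeneList(
            "profiled", frozenset(self.table.gene_ids)
        )
        native = self.table.condition == "native"
        organoid = ~native
        prof_n = profiles.mean_profile_matrix(
            normalize_fraction_umi(self.table.subset_cells(native)),
            self.table.cell_type[native], genes,
        )
        prof_o = profiles.mean_profile_matrix(
            normalize_fraction_umi(self.table.subset_cells(organoid)),
            self.table.cell_type[organoid], genes,
        )
        summary = profiles.profile_correlation(
            prof_n, prof_o, r_threshold=self.params.r_threshold
        )
        out = self.outdir / "correlations.tsv"
        summary.per_gene.round(6).to_frame().rename_axis("gene").to_csv(
            out, sep="\t")
        out_json = self.outdir / "correlation_summary.json"
        out_json.write_text(
            json.dumps(
                {
                    "median_r": round(summary.median_r, 6),
                    "n_above": summary.n_above,
                    "percent_above": summary.percent_above,
                    "threshold": summary.threshold,
                    "n_zero_variance": summary.n_zero_variance,
                },
                indent=2,
            )
        )
        self.correlation = summary
        self._record("correlate", {"correlations": out, "summary": out_json})

    # -------------------------------------------------------------------- run

    def run_all(self) -> dict:
        self.load_data()
        for stage in STAGES_IN_ORDER:
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:  # noqa: BLE001 - abort names the stage
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest_path = self.outdir / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        log_path = self.outdir / "run.log"
        log_path.write_text(
            f"seed={self.params.rng_seed}\nstages={','.join(STAGES_IN_ORDER)}\n"
        )
        return self.manifest


def run_pipeline(config: str | Path | RunConfig) -> dict:
    """Execute every stage from a YAML config path (or RunConfig)."""
    run_cfg = config if isinstance(config, RunConfig) else load_config(config)
    return PipelineRun(run_cfg).run_all()
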