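"""End-to-end pipeline: simulate/load -> preprocess -> QC -> ICA ->
extraction -> annotation -> activity analysis, with a machine-readable
run manifest (seeds, parameters, stage outputs) sufficient to replay the
run bitwise."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .activity import (
    activity_heatmap_table,
    condition_activity_table,
    rank_active_ims,
    tradeoff_correlations,
)
from .annotation import RegulonDB, annotate_imodulons, annotation_table
from .compendium import ExpressionCompendium, load_compendium
from .config import PipelineConfig
from .extraction import extract_imodulons, write_im_genes
from .ica import explained_variance, optica, robust_ica, write_decomposition
from .preprocess import center_to_reference, log_transform, qc_replicates
from .synthetic import SyntheticConfig, generate_compendium, write_regulons_tsv

log = logging.getLogger("modulome")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run artifact directory.

    Each stage writes its outputs under ``output_dir`` and never touches
    another stage's files; ``manifest.json`` records parameters, seeds
    and completed stages.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": config.to_dict(),
        "stages": [],
    }

    def done(stage: str, **info) -> None:
        log.info("stage %s complete %s", stage, info or "")
        manifest["stages"].append({"stage": stage, **info})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    truth = None
    stage = "load"
    try:
        if config.expression_path is None:
            stage = "simulate"
            syn = SyntheticConfig(
                n_genes=config.n_genes,
                n_samples=config.n_samples,
                n_modules=config.n_modules,
                module_size_range=(config.module_size_min, config.module_size_max),
                n_replicate_groups=config.n_replicate_groups,
                replicates_per_group=config.replicates_per_group,
                noise_sd=config.noise_sd,
                activity_sd=config.activity_sd,
                weight_magnitude=config.weight_magnitude,
                regulon_jitter=config.regulon_jitter,
                seed=config.base_seed,
            )
            truth = generate_compendium(syn)
            comp = truth.compendium
            comp.values.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
            comp.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
            write_regulons_tsv(truth.regulons, out / "regulons.tsv")
            db = RegulonDB(universe=set(comp.gene_ids), regulons=truth.regulons)
            done(stage, seed=config.base_seed, n_genes=comp.n_genes, n_samples=comp.n_samples)
        else:
            comp = load_compendium(config.expression_path, config.metadata_path)
            db = None
            if config.regulons_path:
                db = RegulonDB.from_tsv(config.regulons_path, universe=set(comp.gene_ids))
            done(stage, n_genes=comp.n_genes, n_samples=comp.n_samples)

        stage = "preprocess"
        logged = log_transform(comp, pseudocount=config.pseudocount)
        centered = center_to_reference(logged, reference=config.reference_group)
        centered.values.to_csv(out / "centered.tsv", sep="\t", index_label="gene_id")
        done(stage)

        stage = "qc"
        report = qc_replicates(logged)
        (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        try:
            from .plots import plot_qc_histogram

            plot_qc_histogram(report, out / "qc_pccs.svg")
        except Exception as exc:  # plotting must never sink the run
            log.warning("QC figure skipped: %s", exc)
        done(stage, passed=report.passed)

        stage = "ica"
        X = centered.values
        if config.dimension is not None:
            dec = robust_ica(
                X, config.dimension, n_restarts=config.n_restarts,
                base_seed=config.base_seed, tol=config.tolerance,
                max_iter=config.max_iter, cluster_eps=config.cluster_eps,
            )
            done(stage, dimension=config.dimension, n_components=dec.n_components)
        else:
            stage = "optica"
            res = optica(
                X, list(config.optica_candidates), n_restarts=config.n_restarts,
                base_seed=config.base_seed, dominance=config.single_gene_dominance,
                tol=config.tolerance, max_iter=config.max_iter,
                cluster_eps=config.cluster_eps,
            )
            res.table.to_csv(out / "optica.tsv", sep="\t", index=False)
            dec = res.decomposition
            done(stage, selected_dimension=res.selected_dimension,
                 n_components=dec.n_components)
        dec.M.index = X.index
        dec.A.columns = X.columns
        write_decomposition(dec, out)
        ev = explained_variance(X, dec)
        (out / "explained_variance.json").write_text(json.dumps({"explained_variance": ev}))

        stage = "extract"
        ims = extract_imodulons(dec, cutoff=config.k2_cutoff)
        write_im_genes(ims, out / "IM_genes.csv")
        done(stage, n_imodulons=len(ims), n_nonempty=sum(im.size > 0 for im in ims))

        stage = "annotate"
        if config.annotate and db is not None:
            enr, _ = annotate_imodulons(
                ims, db, fdr_cutoff=config.fdr_cutoff,
                intersection_dominance=config.intersection_dominance,
            )
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            annotation_table(ims).to_csv(out / "IM_annotation.csv", index=False)
            done(stage, n_annotated=sum(im.status != "uncharacterized" for im in ims))
        else:
            done(stage, skipped=True)

        stage = "activity"
        profiles = condition_activity_table(dec.A, comp.metadata)
        activity_heatmap_table(profiles).to_csv(out / "activity_by_condition.tsv", sep="\t")
        if config.contrast is not None:
            ranked = rank_active_ims(profiles, tuple(config.contrast), top_k=config.top_k_active)
            ranked.to_csv(out / "active_ims.tsv", sep="\t", index=False)
        comp_ids = dec.component_ids()
        if len(comp_ids) >= 2:
            pairs = [(comp_ids[0], c) for c in comp_ids[1:]]
            tradeoff_correlations(dec.A, pairs).to_csv(out / "tradeoff.tsv", sep="\t", index=False)
        done(stage, explained_variance=ev)
    except StageFailure:
        raise
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    return out
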