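"""One-command end-to-end run: simulate a cohort, fit the signature model,
run every screen, and write all outputs as TSV.

The run is a pure function of (SimConfig, RunConfig): rerunning with the same
configuration reproduces byte-identical outputs.  A run manifest records the
seed, the config digest and the package version.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as iio
from .config import RunConfig
from .enrichment import (
    gsea_preranked,
    rank_genes_by_fold_change,
    score_feature_correlation,
)
from .model import IntegrinSignatureModel
from .regulome import (
    build_regulatory_network,
    filter_mirna_cascade,
    map_probes_to_promoters,
    methylation_screen,
    tf_screen,
)
from .simulate import (
    SimConfig,
    simulate_cohort,
    simulate_omics_layers,
    simulate_score_features,
)

logger = logging.getLogger("integrinscore")

__all__ = ["run_pipeline", "default_omics_targets"]


def default_omics_targets(signature_genes: list[str]) -> pd.DataFrame:
    """Planted layer targets used by the demonstration pipeline: one promoter
    probe per first six signature genes (negative methylation links), three
    miRNAs and three TFs."""
    rows = []
    for i, g in enumerate(signature_genes[:6]):
        rows.append({"layer": "methylation", "feature": f"cg{i:05d}", "gene": g, "rho": -0.5})
    for i, g in enumerate(signature_genes[:3]):
        rows.append({"layer": "mirna", "feature": f"miR-{100 + i}", "gene": g, "rho": -0.45})
    for i, g in enumerate(signature_genes[3:6]):
        rows.append({"layer": "tf", "feature": f"TF{i + 1}", "gene": g, "rho": 0.5})
    return pd.DataFrame(rows)


def run_pipeline(
    sim_config: SimConfig,
    run_config: RunConfig | None = None,
    outdir: str | Path = "pipeline_out",
    gene_sets: dict[str, list[str]] | None = None,
    scale_screen_thresholds: bool = True,
) -> dict:
    """Simulate -> directions -> score -> stratify -> screens -> enrich -> associate.

    Writes expression/clinical/ground-truth inputs plus every stage's result
    table under ``outdir`` and returns the in-memory results keyed by stage.
    """
    cfg = run_config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort, truth = simulate_cohort(sim_config)
    iio.write_matrix_tsv(cohort.expression, outdir / "expression.tsv")
    iio.write_table_tsv(cohort.clinical, outdir / "clinical.tsv")
    iio.write_table_tsv(truth.betas, outdir / "ground_truth_betas.tsv")

    model = IntegrinSignatureModel(
        cohort.expression, cohort.clinical, genes=cohort.signature_genes, config=cfg
    )
    fit = model.fit(seed=cfg.seed)
    fit.write(outdir)

    # omics layers + screens
    targets = default_omics_targets(cohort.signature_genes)
    omics = simulate_omics_layers(cohort, targets, seed=cfg.seed + 11)
    pmap = map_probes_to_promoters(omics.probe_coords, omics.tss, omics.beta_values)
    iio.write_table_tsv(pmap.table, outdir / "promoter_probes.tsv")
    labels = cohort.cancer_labels
    meth = methylation_screen(pmap, omics.beta_values, cohort.expression, labels, cfg)
    iio.write_table_tsv(meth, outdir / "methylation_screen.tsv")

    sig_expr = cohort.expression.loc[cohort.signature_genes]
    validated = targets.loc[targets["layer"] == "mirna", ["feature", "gene"]]
    mirna_cfg_pairs = validated.iloc[: max(1, len(validated) - 1)]  # leave one unvalidated
    mirna_cfg = cfg
    if scale_screen_thresholds:
        # the published count thresholds assume a TCGA-scale cohort; scale them to
        # the simulated cohort so the cascade stages stay exercisable
        n_total = cohort.expression.shape[1]
        scaled = {}
        if cfg.mirna_min_samples >= n_total:
            scaled["mirna_min_samples"] = n_total // 2
        if cfg.mirna_min_cancers >= sim_config.n_cancers:
            scaled["mirna_min_cancers"] = max(1, sim_config.n_cancers - 1)
        if scaled:
            logger.info("scaling miRNA cascade count thresholds to cohort size: %s", scaled)
            mirna_cfg = RunConfig(**{**cfg.to_dict(), **scaled})
    mirna_rec, mirna_final = filter_mirna_cascade(
        omics.mirna, sig_expr, labels, mirna_cfg_pairs, mirna_cfg
    )
    iio.write_table_tsv(mirna_rec, outdir / "mirna_records.tsv")
    iio.write_table_tsv(mirna_final, outdir / "mirna_final_pairs.tsv")

    tf_pairs = targets.loc[targets["layer"] == "tf", ["feature", "gene"]].rename(
        columns={"feature": "tf", "gene": "target"}
    )
    expr_with_tf = pd.concat([cohort.expression, omics.tf_expr])
    tf_rec, tf_top = tf_screen(tf_pairs, expr_with_tf, labels, cohort.signature_genes, cfg)
    iio.write_table_tsv(tf_rec, outdir / "tf_records.tsv")
    iio.write_table_tsv(tf_top, outdir / "tf_top.tsv")

    network = build_regulatory_network(
        mirna_rec[mirna_rec["stage3_validated"]].drop_duplicates(["feature", "gene"]),
        tf_rec[tf_rec["significant"]].drop_duplicates(["feature", "gene"]),
    )
    iio.write_table_tsv(network, outdir / "regulatory_network.tsv")

    # enrichment per cancer on high-vs-low strata
    if gene_sets is None:
        genes_all = list(cohort.expression.index)
        gene_sets = {
            "SIGNATURE_SET": cohort.signature_genes,
            "RANDOM_SET_A": genes_all[:: max(1, len(genes_all) // 20)][:15],
        }
    enr_frames = []
    for cancer in sorted(fit.stratifications):
        sub = fit.scores[fit.scores["cancer_type"] == cancer]
        strata = sub.set_index("sample")["stratum"]
        ranked = rank_genes_by_fold_change(
            cohort.expression[strata.index],
            strata,
            pseudocount=cfg.deg_pseudocount,
            deg_abs_log2fc=cfg.deg_abs_log2fc,
            deg_fdr=cfg.deg_fdr,
        )
        enr = gsea_preranked(
            ranked,
            gene_sets,
            weight=cfg.gsea_weight,
            n_perm=cfg.gsea_n_perm,
            seed=cfg.seed + 23,
            min_size=cfg.gsea_min_size,
            fdr_threshold=cfg.gsea_fdr,
        )
        enr.insert(0, "cancer", cancer)
        enr_frames.append(enr)
    enrichment = pd.concat(enr_frames, ignore_index=True)
    iio.write_table_tsv(enrichment, outdir / "enrichment.tsv")

    # score-correlated features
    score_series = fit.scores.set_index("sample")["score"]
    feats = simulate_score_features(
        score_series,
        immune_targets={"CD8_T": -0.5, "Treg": 0.4},
        feature_targets={"cycle_step_1": 0.3, "drug_A_ic50": 0.35, "drug_B_ic50": -0.35},
        icb_coefficient=-1.0,
        seed=cfg.seed + 31,
    )
    immune_assoc = score_feature_correlation(fit.scores, feats.immune_fractions, "immune", cfg)
    drug_assoc = score_feature_correlation(
        fit.scores, feats.features.loc[["drug_A_ic50", "drug_B_ic50"]], "drug", cfg
    )
    iio.write_table_tsv(immune_assoc, outdir / "immune_association.tsv")
    iio.write_table_tsv(drug_assoc, outdir / "drug_association.tsv")

    manifest = {
        "seed": cfg.seed,
        "sim_seed": sim_config.seed,
        "config_sha256": cfg.digest(),
        "version": __version__,
        "n_samples": int(cohort.expression.shape[1]),
        "n_genes": int(cohort.expression.shape[0]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", outdir)
    return {
        "cohort": cohort,
        "truth": truth,
        "fit": fit,
        "methylation": meth,
        "mirna_records": mirna_rec,
        "mirna_final": mirna_final,
        "tf_records": tf_rec,
        "tf_top": tf_top,
        "network": network,
        "enrichment": enrichment,
        "immune_association": immune_assoc,
        "drug_association": drug_assoc,
        "manifest": manifest,
    }
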