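"""Mechanism screens: promoter-probe methylation mapping, layered Spearman
screens (methylation / miRNA / TF), CNV-expression association, and the miRNA
filter cascade.

All screens share one correlation primitive (tie-aware Spearman with a
t-approximation p-value) and one filter predicate: magnitude thresholds are
inclusive (|rho| >= cut), p-value thresholds strict (p < cut), and count
thresholds strict ("more than" N).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig

logger = logging.getLogger("integrinscore")

__all__ = [
    "spearman",
    "passes_correlation_filter",
    "PromoterProbeMap",
    "map_probes_to_promoters",
    "methylation_screen",
    "filter_mirna_cascade",
    "tf_screen",
    "cnv_expression_association",
    "build_regulatory_network",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
]

#: promoter window in transcription orientation: [TSS - upstream, TSS + downstream)
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 200


def spearman(x, y, p_method: str = "t", n_perm: int = 10000, seed: int = 0):
    """Spearman rank correlation with pairwise deletion of missing values.

    Returns (rho, p, n).  ``p_method="t"`` (default) uses the t-approximation on
    n - 2 degrees of freedom for all n; ``"permutation"`` uses an exact
    enumeration for n <= 8 and a seeded Monte Carlo permutation null otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: constant input after filtering")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if p_method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    elif p_method == "permutation":
        if n <= 8:
            count = total = 0
            for perm in itertools.permutations(range(n)):
                r = np.corrcoef(rx, ry[list(perm)])[0, 1]
                count += abs(r) >= abs(rho) - 1e-12
                total += 1
            p = count / total
        else:
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_perm):
                r = np.corrcoef(rx, ry[rng.permutation(n)])[0, 1]
                count += abs(r) >= abs(rho) - 1e-12
            p = (1 + count) / (1 + n_perm)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return rho, p, n


def passes_correlation_filter(rho: float, p: float, rho_min: float, p_max: float) -> bool:
    """Shared screen rule: inclusive on |rho|, strict on p."""
    return abs(rho) >= rho_min and p < p_max


# ---------------------------------------------------------------------------
# promoter-probe mapping
# ---------------------------------------------------------------------------

@dataclass
class PromoterProbeMap:
    """gene -> selected promoter probe, plus per-gene candidate counts."""

    table: pd.DataFrame  # gene, probe, chrom, pos, mean_beta, n_candidates
    n_unmapped: int

    def probe_for(self, gene: str) -> str:
        return str(self.table.set_index("gene").loc[gene, "probe"])


def _in_promoter(pos: int, tss: int, strand: str) -> bool:
    offset = pos - tss if strand == "+" else tss - pos
    return -PROMOTER_UPSTREAM <= offset < PROMOTER_DOWNSTREAM


def map_probes_to_promoters(
    probes: pd.DataFrame,
    tss_table: pd.DataFrame,
    beta_matrix: pd.DataFrame,
) -> PromoterProbeMap:
    """Select one promoter probe per gene: in-window, maximal mean beta-value.

    The window runs 1000 bp upstream to 200 bp downstream of the TSS in
    transcription orientation.  Ties on mean beta resolve to the smaller
    coordinate; genes with no in-window probe are omitted with a logged count.
    ``probes`` needs columns (probe, chrom, pos); ``tss_table`` columns
    (gene, chrom, tss, strand).
    """
    known_chroms = set(tss_table["chrom"])
    rows = []
    n_unmapped = 0
    mean_beta = beta_matrix.mean(axis=1)
    for g in tss_table.itertuples(index=False):
        cands = []
        for p in probes.itertuples(index=False):
            if p.chrom not in known_chroms:
                continue
            if p.chrom == g.chrom and _in_promoter(int(p.pos), int(g.tss), g.strand):
                if p.probe not in beta_matrix.index:
                    warnings.warn(f"probe {p.probe!r} absent from beta matrix; skipped")
                    continue
                cands.append((p.probe, int(p.pos), float(mean_beta[p.probe])))
        if not cands:
            n_unmapped += 1
            continue
        cands.sort(key=lambda c: (-c[2], c[1]))  # max mean beta, then smaller coordinate
        probe, pos, mb = cands[0]
        rows.append(
            {"gene": g.gene, "probe": probe, "chrom": g.chrom, "pos": pos,
             "mean_beta": mb, "n_candidates": len(cands)}
        )
    unknown = set(probes["chrom"]) - known_chroms
    if unknown:
        warnings.warn(f"probes on unknown chromosome(s) {sorted(unknown)} skipped")
    if not rows:
        raise ValueError("no gene has a probe in its promoter window")
    if n_unmapped:
        logger.info("%d gene(s) without an in-window promoter probe omitted", n_unmapped)
    return PromoterProbeMap(table=pd.DataFrame(rows), n_unmapped=n_unmapped)


# ---------------------------------------------------------------------------
# correlation screens
# ---------------------------------------------------------------------------

def _per_cancer_records(
    feature_matrix: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    pairs: list[tuple[str, str]],
    cancer_labels: pd.Series,
    layer: str,
    rho_min: float,
    p_max: float,
) -> pd.DataFrame:
    """Spearman of (feature, gene) pairs within each cancer, with filter flags."""
    rows = []
    shared = [s for s in gene_matrix.columns if s in feature_matrix.columns]
    labels = cancer_labels.reindex(shared)
    for cancer in sorted(labels.dropna().unique()):
        cols = [s for s, c in zip(shared, labels) if c == cancer]
        for feature, gene in pairs:
            if feature not in feature_matrix.index or gene not in gene_matrix.index:
                continue
            x = feature_matrix.loc[feature, cols].to_numpy(float)
            y = gene_matrix.loc[gene, cols].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                warnings.warn(
                    f"{layer}: {feature}~{gene} in {cancer}: fewer than 3 matched "
                    "samples; skipped"
                )
                continue
            try:
                rho, p, n = spearman(x, y)
            except ValueError:
                warnings.warn(f"{layer}: {feature}~{gene} in {cancer}: degenerate; skipped")
                continue
            rows.append(
                {
                    "cancer": cancer,
                    "layer": layer,
                    "feature": feature,
                    "gene": gene,
                    "rho": rho,
                    "p": p,
                    "n": n,
                    "significant": passes_correlation_filter(rho, p, rho_min, p_max),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cancer", "layer", "feature", "gene", "rho", "p", "n", "significant"],
    )


def methylation_screen(
    promoter_map: PromoterProbeMap,
    beta_matrix: pd.DataFrame,
    expr: pd.DataFrame,
    cancer_labels: pd.Series,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-cancer Spearman between each gene's promoter probe and its expression.

    Significance at |rho| >= meth_rho (default 0.15) and p < meth_p (0.05).
    """
    config = config or RunConfig()
    pairs = [(r.probe, r.gene) for r in promoter_map.table.itertuples(index=False)]
    rec = _per_cancer_records(
        beta_matrix, expr, pairs, cancer_labels, "methylation", config.meth_rho, config.meth_p
    )
    n_neg = int(((rec["rho"] < 0) & rec["significant"]).sum())
    n_pos = int(((rec["rho"] > 0) & rec["significant"]).sum())
    logger.info("methylation screen: %d negative, %d positive significant pairs", n_neg, n_pos)
    return rec


def filter_mirna_cascade(
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    cancer_labels: pd.Series,
    validated_pairs: pd.DataFrame | None,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Three-stage miRNA-gene filter cascade.

    Stage 1 keeps miRNAs expressed above ``mirna_expr_threshold`` in strictly
    more than ``mirna_min_samples`` samples pan-cancer.  Stage 2 keeps pairs
    significant (|rho| >= mirna_rho, p < mirna_p) in strictly more than
    ``mirna_min_cancers`` cancer types.  Stage 3 intersects with the validated
    pair table (columns feature, gene); an empty/absent table skips stage 3
    with a loud warning.  Returns (per-cancer records with stage flags, final
    pair list).
    """
    config = config or RunConfig()
    expressed_counts = (mirna_expr > config.mirna_expr_threshold).sum(axis=1)
    stage1 = set(expressed_counts.index[expressed_counts > config.mirna_min_samples])
    pairs = [(m, g) for m in mirna_expr.index if m in stage1 for g in gene_expr.index]
    rec = _per_cancer_records(
        mirna_expr.loc[sorted(stage1)] if stage1 else mirna_expr.iloc[:0],
        gene_expr,
        pairs,
        cancer_labels,
        "miRNA",
        config.mirna_rho,
        config.mirna_p,
    )
    rec["stage1_expressed"] = True  # records only exist for stage-1 survivors
    if rec.empty:
        counts = pd.Series(dtype=int)
    else:
        counts = rec.groupby(["feature", "gene"])["significant"].sum()
    stage2_pairs = set(counts.index[counts > config.mirna_min_cancers])
    rec["stage2_multicancer"] = [
        (f, g) in stage2_pairs for f, g in zip(rec["feature"], rec["gene"])
    ]

    have_validation = validated_pairs is not None and len(validated_pairs) > 0
    if not have_validation:
        warnings.warn(
            "validated miRNA-target table is empty: stage 3 (database validation) SKIPPED; "
            "final pairs are unvalidated"
        )
        validated = stage2_pairs
    else:
        vset = {(f, g) for f, g in zip(validated_pairs["feature"], validated_pairs["gene"])}
        validated = stage2_pairs & vset
    rec["stage3_validated"] = [
        (f, g) in validated for f, g in zip(rec["feature"], rec["gene"])
    ]
    final = pd.DataFrame(sorted(validated), columns=["feature", "gene"])
    return rec, final


def tf_screen(
    tf_target_pairs: pd.DataFrame,
    expr: pd.DataFrame,
    cancer_labels: pd.Series,
    signature_genes: list[str],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TF-target expression correlations and the top-N TF ranking.

    Pairs are significant at |rho| >= tf_rho (default 0.2) and p < tf_p (0.01).
    TFs are ranked by their count of distinct annotated signature-gene targets
    (top ``tf_top_n`` reported, with per-cancer percent positive/negative among
    significant pairs attached).
    """
    config = config or RunConfig()
    pairs = []
    for r in tf_target_pairs.itertuples(index=False):
        if r.tf not in expr.index:
            warnings.warn(f"TF {r.tf!r} absent from expression matrix; pairs skipped")
            continue
        if r.target in expr.index:
            pairs.append((r.tf, r.target))
    rec = _per_cancer_records(
        expr, expr, pairs, cancer_labels, "TF", config.tf_rho, config.tf_p
    )

    sig_targets = (
        tf_target_pairs[tf_target_pairs["target"].isin(signature_genes)]
        .groupby("tf")["target"]
        .nunique()
        .sort_values(ascending=False, kind="stable")
    )
    top = sig_targets.head(config.tf_top_n)
    top_rows = []
    for tf, n_targets in top.items():
        sub = rec[(rec["feature"] == tf) & rec["significant"]]
        n_sig = len(sub)
        top_rows.append(
            {
                "tf": tf,
                "n_signature_targets": int(n_targets),
                "n_significant_pairs": n_sig,
                "pct_positive": 100.0 * (sub["rho"] > 0).mean() if n_sig else np.nan,
                "pct_negative": 100.0 * (sub["rho"] < 0).mean() if n_sig else np.nan,
            }
        )
    return rec, pd.DataFrame(top_rows)


def cnv_expression_association(
    cnv_states: pd.DataFrame,
    expr: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene expression comparison across amplification / diploid / deletion.

    Kruskal-Wallis across the three states plus pairwise two-sided Wilcoxon
    rank-sum tests and per-state medians; genes with any state under 3 samples
    are skipped with a warning.
    """
    rows = []
    shared = [s for s in expr.columns if s in cnv_states.columns]
    for gene in cnv_states.index:
        if gene not in expr.index:
            continue
        states = cnv_states.loc[gene, shared]
        vals = expr.loc[gene, shared].to_numpy(float)
        groups = {
            st: vals[(states == st).to_numpy()]
            for st in ("amplification", "diploid", "deletion")
        }
        if any(len(v) < 3 for v in groups.values()):
            warnings.warn(f"gene {gene!r}: a CNV state has fewer than 3 samples; skipped")
            continue
        kw_stat, kw_p = stats.kruskal(*groups.values())
        row = {
            "gene": gene,
            "kruskal_stat": float(kw_stat),
            "kruskal_p": float(kw_p),
            "median_amplification": float(np.median(groups["amplification"])),
            "median_diploid": float(np.median(groups["diploid"])),
            "median_deletion": float(np.median(groups["deletion"])),
        }
        for a, b in (("amplification", "diploid"), ("amplification", "deletion"),
                     ("diploid", "deletion")):
            _, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            row[f"wilcoxon_p_{a[:3]}_{b[:3]}"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def build_regulatory_network(
    mirna_records: pd.DataFrame,
    tf_records: pd.DataFrame,
    mirna_tf_links: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tripartite miRNA / TF / gene edge list from finalized screen records.

    ``mirna_records`` and ``tf_records`` need columns (feature, gene, rho);
    optional ``mirna_tf_links`` columns (mirna, tf).  Duplicate edges collapse
    to the first occurrence.
    """
    rows = []
    for rec, src_type in ((mirna_records, "miRNA"), (tf_records, "TF")):
        if rec is None or rec.empty:
            continue
        for r in rec.itertuples(index=False):
            rho = float(getattr(r, "rho", np.nan))
            rows.append(
                {
                    "source_type": src_type,
                    "source": r.feature,
                    "target_type": "gene",
                    "target": r.gene,
                    "sign": "+" if rho >= 0 else "-",
                    "rho": rho,
                }
            )
    if mirna_tf_links is not None and not mirna_tf_links.empty:
        for r in mirna_tf_links.itertuples(index=False):
            rows.append(
                {
                    "source_type": "TF",
                    "source": r.tf,
                    "target_type": "miRNA",
                    "target": r.mirna,
                    "sign": ".",
                    "rho": np.nan,
                }
            )
    edges = pd.DataFrame(
        rows, columns=["source_type", "source", "target_type", "target", "sign", "rho"]
    )
    return edges.drop_duplicates(
        subset=["source_type", "source", "target_type", "target"], keep="first"
    ).reset_index(drop=True)
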