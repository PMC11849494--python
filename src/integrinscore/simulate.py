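"""Synthetic multi-cancer cohorts with planted, recoverable ground truth.

The generator emulates the statistical structure every downstream stage
assumes, without imitating any particular real cohort:

* log-normal TPM-like expression with cancer-specific gene means;
* survival times from a Weibull proportional-hazards model whose linear
  predictor sums planted per-gene log-hazard coefficients over standardized
  log-expression, with independent censoring calibrated to a target rate;
* optional planted expression clusters (distinct mean signature profiles) and
  per-gene copy-number states shifting log-expression before survival is drawn;
* methylation / miRNA / TF layers tied to gene expression through a Gaussian
  copula on ranks, so Spearman targets survive the marginal transforms;
* immune-fraction, feature, drug-response and ICB-response tables correlated
  with a supplied per-sample score the same way.

Everything is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INTEGRIN_GENES",
    "SimConfig",
    "CnvConfig",
    "CohortBundle",
    "GroundTruth",
    "OmicsLayers",
    "ScoreFeatureBundle",
    "simulate_cohort",
    "simulate_omics_layers",
    "simulate_cnv_labels",
    "simulate_score_features",
]

#: the 26 human integrin subunit genes (18 alpha + 8 beta)
INTEGRIN_GENES = (
    "ITGA1", "ITGA2", "ITGA2B", "ITGA3", "ITGA4", "ITGA5", "ITGA6", "ITGA7",
    "ITGA8", "ITGA9", "ITGA10", "ITGA11", "ITGAD", "ITGAE", "ITGAL", "ITGAM",
    "ITGAV", "ITGAX", "ITGB1", "ITGB2", "ITGB3", "ITGB4", "ITGB5", "ITGB6",
    "ITGB7", "ITGB8",
)


@dataclass
class CnvConfig:
    """Copy-number simulation: state frequencies and per-state log-expression shift."""

    freq_amplification: float = 0.15
    freq_diploid: float = 0.70
    freq_deletion: float = 0.15
    effect: float = 1.0  # mean log-expression shift (+ for amplification)

    def __post_init__(self) -> None:
        total = self.freq_amplification + self.freq_diploid + self.freq_deletion
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"CNV state frequencies must sum to 1, got {total}")


@dataclass
class SimConfig:
    """Conditions of a simulated multi-cancer cohort.

    Defaults: 3 cancer types of 200 patients, the 26-gene integrin signature
    plus 100 background genes, a quarter of signature genes planted oncogenic
    and a quarter protective per cancer at |log-hazard| = log 2 per expression
    SD, Weibull(shape 1.2) baseline with ~5-year median survival and 30%
    independent censoring.
    """

    n_cancers: int = 3
    samples_per_cancer: int = 200
    n_signature_genes: int = 26
    n_background_genes: int = 100
    frac_oncogenic: float = 0.25
    frac_protective: float = 0.25
    effect_sizes: tuple[float, ...] = (float(np.log(2.0)),)  # |beta| grid, cycled
    weibull_shape: float = 1.2
    weibull_scale: float = 1800.0  # days
    censoring: float = 0.3
    pfs_factor_range: tuple[float, float] = (0.4, 0.9)
    expr_sd: float = 1.0  # within-cancer log-expression SD
    mean_loc: float = 2.0  # cancer-specific gene mean: Normal(mean_loc, mean_spread)
    mean_spread: float = 0.5
    n_clusters: int = 1
    cluster_separation: float = 2.0  # SD of per-gene centroid offsets when n_clusters > 1
    cnv: CnvConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_cancer < 20:
            raise ValueError("need at least 20 samples per cancer")
        if not 0 <= self.censoring <= 0.9:
            raise ValueError("censoring target must lie in [0, 0.9]")
        if self.frac_oncogenic + self.frac_protective > 1:
            raise ValueError("oncogenic + protective fractions exceed 1")

    @property
    def signature_genes(self) -> list[str]:
        base = list(INTEGRIN_GENES)
        if self.n_signature_genes <= len(base):
            return base[: self.n_signature_genes]
        extra = [f"SIG{i:03d}" for i in range(len(base), self.n_signature_genes)]
        return base + extra

    @property
    def background_genes(self) -> list[str]:
        return [f"BG{i:04d}" for i in range(self.n_background_genes)]


@dataclass
class CohortBundle:
    """Simulated inputs as the analysis stages see them."""

    expression: pd.DataFrame  # genes x samples, TPM-like
    clinical: pd.DataFrame  # sample, cancer_type, os/pfs time+event
    signature_genes: list[str]

    @property
    def cancer_labels(self) -> pd.Series:
        return self.clinical.set_index("sample")["cancer_type"].reindex(
            self.expression.columns
        )


@dataclass
class GroundTruth:
    """Planted truth, written separately and never read by analysis stages."""

    betas: pd.DataFrame  # columns: cancer, gene, beta, direction
    linear_predictor: pd.Series  # per sample, the true Weibull-PH log-hazard term
    cluster_labels: pd.Series  # per sample (all 0 when n_clusters == 1)
    cnv_states: pd.DataFrame | None  # genes x samples, {amplification,diploid,deletion}
    cnv_effect: float | None

    def direction_of(self, cancer: str, gene: str) -> str:
        sub = self.betas[(self.betas["cancer"] == cancer) & (self.betas["gene"] == gene)]
        return str(sub["direction"].iloc[0])


def _direction_from_beta(beta: float) -> str:
    if beta > 0:
        return "oncogenic"
    if beta < 0:
        return "protective"
    return "neutral"


def _calibrate_censoring(
    event_times: np.ndarray, target: float, u: np.ndarray, tol: float = 0.02
) -> np.ndarray:
    """Exponential censoring times achieving the target censoring fraction.

    Uses fixed uniform draws ``u`` so the result is a deterministic function of
    the inputs; the rate is found by bisection (censoring fraction is monotone
    in the rate).  Raises if the target is unreachable within tolerance.
    """
    if target <= 0:
        return np.full_like(event_times, np.inf)

    def frac_censored(log_rate: float) -> float:
        c = -np.log(u) / np.exp(log_rate)
        return float(np.mean(c < event_times))

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac_censored(mid) < target:
            lo = mid
        else:
            hi = mid
    achieved = frac_censored(hi)
    if abs(achieved - target) > tol:
        raise RuntimeError(
            f"censoring calibration failed: target {target}, achieved {achieved:.3f}"
        )
    return -np.log(u) / np.exp(hi)


def simulate_cnv_labels(
    genes: list[str],
    samples: list[str],
    cnv: CnvConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample, per-gene CNV states and the implied log-expression shifts.

    Returns (states, shifts): states in {amplification, diploid, deletion}; the
    shift is +effect for amplified, -effect for deleted, 0 for diploid.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = [cnv.freq_amplification, cnv.freq_diploid, cnv.freq_deletion]
    draw = rng.choice(3, size=(len(genes), len(samples)), p=probs)
    names = np.array(["amplification", "diploid", "deletion"])
    states = pd.DataFrame(names[draw], index=genes, columns=samples)
    shifts = pd.DataFrame(
        np.where(draw == 0, cnv.effect, np.where(draw == 2, -cnv.effect, 0.0)),
        index=genes,
        columns=samples,
    )
    return states, shifts


def simulate_cohort(config: SimConfig) -> tuple[CohortBundle, GroundTruth]:
    """Generate a multi-cancer cohort under a Weibull proportional-hazards model.

    Per cancer: log-expression L_g = mu_{c,g} + cluster offset + CNV shift +
    Normal(0, expr_sd); TPM = exp(L).  The linear predictor is
    eta_i = sum_g beta_g z_gi over planted signature genes, with z the
    standardized log-expression within the cancer, and event times follow
    S(t | eta) = exp(-(t/scale)^shape * e^eta).  PFS is the event time scaled
    by a per-sample uniform factor with its own calibrated censoring.
    """
    rng = np.random.default_rng(config.seed)
    sig = config.signature_genes
    genes = sig + config.background_genes
    k, s = config.weibull_shape, config.weibull_scale

    expr_blocks, clin_rows, beta_rows = [], [], []
    lp_all, cluster_all = {}, {}
    cnv_states_blocks = []

    n_onc = int(round(config.frac_oncogenic * len(sig)))
    n_prot = int(round(config.frac_protective * len(sig)))
    grid = np.asarray(config.effect_sizes, float)

    for ci in range(config.n_cancers):
        cancer = f"C{ci + 1:02d}"
        n = config.samples_per_cancer
        samples = [f"{cancer}-S{j:04d}" for j in range(n)]

        mu = rng.normal(config.mean_loc, config.mean_spread, size=len(genes))
        L = mu[:, None] + rng.normal(0.0, config.expr_sd, size=(len(genes), n))

        if config.n_clusters > 1:
            labels = rng.integers(0, config.n_clusters, size=n)
            centroids = rng.normal(
                0.0, config.cluster_separation, size=(config.n_clusters, len(sig))
            )
            L[: len(sig), :] += centroids[labels].T
        else:
            labels = np.zeros(n, dtype=int)

        if config.cnv is not None:
            states, shifts = simulate_cnv_labels(sig, samples, config.cnv, rng)
            L[: len(sig), :] += shifts.to_numpy()
            cnv_states_blocks.append(states)

        # planted directions: random subset of signature genes per cancer
        perm = rng.permutation(len(sig))
        betas = np.zeros(len(sig))
        mags = grid[np.arange(n_onc + n_prot) % grid.size]
        betas[perm[:n_onc]] = mags[:n_onc]
        betas[perm[n_onc : n_onc + n_prot]] = -mags[n_onc:]
        for g, b in zip(sig, betas):
            beta_rows.append(
                {"cancer": cancer, "gene": g, "beta": float(b),
                 "direction": _direction_from_beta(b)}
            )

        Lsig = L[: len(sig), :]
        z = (Lsig - Lsig.mean(axis=1, keepdims=True)) / Lsig.std(axis=1, keepdims=True)
        eta = betas @ z

        # Weibull PH: T = scale * (E / e^eta)^(1/shape), E ~ Exp(1)
        T = s * (rng.exponential(1.0, size=n) / np.exp(eta)) ** (1.0 / k)
        C = _calibrate_censoring(T, config.censoring, rng.uniform(size=n))
        os_time = np.minimum(T, C)
        os_event = (T <= C).astype(int)

        lo, hi = config.pfs_factor_range
        T_pfs = T * rng.uniform(lo, hi, size=n)
        C_pfs = _calibrate_censoring(T_pfs, config.censoring, rng.uniform(size=n))
        pfs_time = np.minimum(T_pfs, C_pfs)
        pfs_event = (T_pfs <= C_pfs).astype(int)

        expr_blocks.append(pd.DataFrame(np.exp(L), index=genes, columns=samples))
        for j, smp in enumerate(samples):
            clin_rows.append(
                {
                    "sample": smp,
                    "cancer_type": cancer,
                    "os_time": float(os_time[j]),
                    "os_event": int(os_event[j]),
                    "pfs_time": float(pfs_time[j]),
                    "pfs_event": int(pfs_event[j]),
                }
            )
            lp_all[smp] = float(eta[j])
            cluster_all[smp] = int(labels[j])

    expression = pd.concat(expr_blocks, axis=1)
    clinical = pd.DataFrame(clin_rows)
    bundle = CohortBundle(expression=expression, clinical=clinical, signature_genes=sig)
    truth = GroundTruth(
        betas=pd.DataFrame(beta_rows),
        linear_predictor=pd.Series(lp_all, name="linear_predictor"),
        cluster_labels=pd.Series(cluster_all, name="cluster"),
        cnv_states=pd.concat(cnv_states_blocks, axis=1) if cnv_states_blocks else None,
        cnv_effect=config.cnv.effect if config.cnv is not None else None,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# copula-coupled layers
# ---------------------------------------------------------------------------

def _copula_latent(anchor: np.ndarray, rho_s: float, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal latent with target *Spearman* correlation to ``anchor``.

    The anchor is reduced to normal scores of its ranks, so only its ordering
    matters; the Pearson parameter is 2 sin(pi * rho_s / 6), the inverse of the
    Gaussian-copula Spearman map.
    """
    if abs(rho_s) >= 0.95:
        raise ValueError(f"|target Spearman| must be < 0.95, got {rho_s}")
    n = anchor.size
    ranks = stats.rankdata(anchor, method="average")
    zx = stats.norm.ppf(ranks / (n + 1.0))
    zx = (zx - zx.mean()) / zx.std()
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    return r * zx + np.sqrt(1.0 - r * r) * rng.standard_normal(n)


@dataclass
class OmicsLayers:
    """Methylation / miRNA / TF layers tied to a cohort by planted correlations."""

    beta_values: pd.DataFrame  # probes x samples, in (0, 1)
    probe_coords: pd.DataFrame  # probe, chrom, pos
    tss: pd.DataFrame  # gene, chrom, tss, strand (BED-convention TSS)
    mirna: pd.DataFrame  # miRNAs x samples, log-normal scale
    tf_expr: pd.DataFrame  # TFs x samples, log-normal scale
    targets: pd.DataFrame  # layer, feature, gene, rho (the planted targets)


def _gene_layout(genes: list[str]) -> pd.DataFrame:
    """Deterministic genome layout: genes spaced along chr1, alternating strand."""
    rows = []
    for i, g in enumerate(genes):
        start = 10_000 + 50_000 * i
        strand = "+" if i % 2 == 0 else "-"
        rows.append({"gene": g, "chrom": "chr1", "tss": start, "strand": strand})
    return pd.DataFrame(rows)


def simulate_omics_layers(
    cohort: CohortBundle,
    targets: pd.DataFrame,
    seed: int = 0,
    n_decoy_probes: int = 5,
    n_decoy_features: int = 5,
) -> OmicsLayers:
    """Generate methylation, miRNA and TF layers with planted Spearman links.

    ``targets`` has columns (layer, feature, gene, rho) with layer in
    {methylation, mirna, tf}; each feature is coupled to its gene's expression
    ranks through a Gaussian copula and then pushed through the layer marginal
    (logistic map into (0,1) for beta-values, log-normal for miRNA/TF).  Planted
    methylation probes land inside their gene's promoter window (within 1000 bp
    upstream to 200 bp downstream of the TSS, in transcription orientation);
    decoy probes land well outside every window.
    """
    rng = np.random.default_rng(seed)
    required = {"layer", "feature", "gene", "rho"}
    if not required.issubset(targets.columns):
        raise ValueError(f"targets must have columns {sorted(required)}")
    expr = cohort.expression
    samples = list(expr.columns)
    tss = _gene_layout(list(expr.index))
    tss_idx = tss.set_index("gene")

    beta_rows, beta_index, probe_rows = [], [], []
    mirna_rows, mirna_index = [], []
    tf_rows, tf_index = [], []

    for rec in targets.itertuples(index=False):
        if rec.gene not in expr.index:
            raise ValueError(f"target gene {rec.gene!r} not in cohort expression")
        latent = _copula_latent(expr.loc[rec.gene].to_numpy(float), float(rec.rho), rng)
        if rec.layer == "methylation":
            offset = rng.normal(0.0, 0.5)
            beta_rows.append(1.0 / (1.0 + np.exp(-(latent + offset))))
            beta_index.append(rec.feature)
            row = tss_idx.loc[rec.gene]
            sign = 1 if row["strand"] == "+" else -1
            probe_rows.append(
                {"probe": rec.feature, "chrom": row["chrom"], "pos": int(row["tss"] - sign * 400)}
            )
        elif rec.layer == "mirna":
            mirna_rows.append(np.exp(0.8 * latent + 1.0))
            mirna_index.append(rec.feature)
        elif rec.layer == "tf":
            tf_rows.append(np.exp(0.8 * latent + 2.0))
            tf_index.append(rec.feature)
        else:
            raise ValueError(f"unknown layer {rec.layer!r}")

    n = len(samples)
    for i in range(n_decoy_probes):
        name = f"cg_decoy{i:03d}"
        beta_rows.append(1.0 / (1.0 + np.exp(-rng.standard_normal(n))))
        beta_index.append(name)
        gi = i % len(tss)
        probe_rows.append(
            {"probe": name, "chrom": "chr1", "pos": int(tss["tss"].iloc[gi] + 10_000)}
        )
    for i in range(n_decoy_features):
        mirna_rows.append(np.exp(0.8 * rng.standard_normal(n) + 1.0))
        mirna_index.append(f"miR-decoy-{i}")
        tf_rows.append(np.exp(0.8 * rng.standard_normal(n) + 2.0))
        tf_index.append(f"TFdecoy{i}")

    return OmicsLayers(
        beta_values=pd.DataFrame(beta_rows, index=beta_index, columns=samples),
        probe_coords=pd.DataFrame(probe_rows),
        tss=tss,
        mirna=pd.DataFrame(mirna_rows, index=mirna_index, columns=samples),
        tf_expr=pd.DataFrame(tf_rows, index=tf_index, columns=samples),
        targets=targets.copy(),
    )


@dataclass
class ScoreFeatureBundle:
    """Immune / feature / ICB tables correlated with a per-sample score."""

    immune_fractions: pd.DataFrame  # cell types x samples, columns sum to 1
    features: pd.DataFrame  # feature x samples (cycle steps, modulators, IC50, ...)
    icb_response: pd.Series | None  # sample -> "responder"/"non-responder"


def simulate_score_features(
    score: pd.Series,
    immune_targets: dict[str, float] | None = None,
    feature_targets: dict[str, float] | None = None,
    icb_coefficient: float | None = None,
    n_filler_cells: int = 5,
    seed: int = 0,
) -> ScoreFeatureBundle:
    """Feature tables copula-correlated with a given score vector.

    Immune cell fractions are generated as exponentiated latents and
    renormalized to sum to 1 per sample (at least 2 cell types required); other
    features keep the log-normal marginal.  ICB response is Bernoulli with
    logit = icb_coefficient * standardized score.
    """
    rng = np.random.default_rng(seed)
    vals = score.to_numpy(float)
    n = vals.size
    immune_targets = dict(immune_targets or {})
    feature_targets = dict(feature_targets or {})

    cells = {}
    for cell, rho in immune_targets.items():
        cells[cell] = np.exp(_copula_latent(vals, rho, rng))
    for i in range(n_filler_cells):
        cells[f"filler_cell_{i}"] = np.exp(rng.standard_normal(n))
    if len(cells) < 2:
        raise ValueError("immune fractions need at least 2 cell types")
    immune = pd.DataFrame(cells, index=score.index).T
    immune = immune / immune.sum(axis=0)

    feats = {
        name: np.exp(0.8 * _copula_latent(vals, rho, rng) + 1.0)
        for name, rho in feature_targets.items()
    }
    features = pd.DataFrame(feats, index=score.index).T

    icb = None
    if icb_coefficient is not None:
        zs = (vals - vals.mean()) / vals.std() if vals.std() > 0 else np.zeros(n)
        p = 1.0 / (1.0 + np.exp(-icb_coefficient * zs))
        icb = pd.Series(
            np.where(rng.uniform(size=n) < p, "responder", "non-responder"),
            index=score.index,
            name="icb_response",
        )
    return ScoreFeatureBundle(immune_fractions=immune, features=features, icb_response=icb)
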