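"""Expression normalization, the integrin score, signature activities, and
score-based patient stratification.

The score for a sample is the sum of normalized expression (within-cancer
z-scores of log2(TPM+1)) over its cancer's oncogenic signature genes minus the
sum over its protective genes; neutral genes contribute nothing:

    score_i = sum_{g oncogenic} z_gi - sum_{g protective} z_gi

Patients are then split into score-high and score-low strata at the optimal
cutpoint of the score itself (maximally selected rank statistic), and the two
strata's survival compared by log-rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import (
    DIRECTION_NEUTRAL,
    DIRECTION_ONCOGENIC,
    DIRECTION_PROTECTIVE,
    CutpointResult,
    KaplanMeierEstimate,
    km_estimate,
    logrank_test,
    max_rank_cutpoint,
)

logger = logging.getLogger("integrinscore")

__all__ = [
    "normalize_expression",
    "compute_integrin_score",
    "stratify_by_score",
    "signature_activity",
    "StratificationResult",
]


def normalize_expression(expr: pd.DataFrame, cancer_labels: pd.Series) -> pd.DataFrame:
    """Within-cancer z-scores of log2(TPM+1), genes x samples.

    Constant genes (within a cancer) map to all-zero rows; cancer groups of
    fewer than 3 samples are an error.
    """
    cancer_labels = cancer_labels.reindex(expr.columns)
    if cancer_labels.isna().any():
        missing = list(expr.columns[cancer_labels.isna()])[:5]
        raise ValueError(f"no cancer label for sample(s) {missing}")
    log2 = np.log2(expr + 1.0)
    out = pd.DataFrame(index=expr.index, columns=expr.columns, dtype=float)
    for cancer, cols in expr.columns.to_series().groupby(cancer_labels, sort=False):
        cols = list(cols)
        if len(cols) < 3:
            raise ValueError(f"cancer group {cancer!r} has {len(cols)} samples; need >= 3")
        block = log2[cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=0)
        z = block.sub(mu, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
        out[cols] = z
    return out


def compute_integrin_score(
    norm_expr: pd.DataFrame,
    directions: pd.DataFrame,
    cancer_labels: pd.Series,
    mode: str = "significant",
) -> pd.DataFrame:
    """Per-sample signature score from a gene-direction table.

    ``directions`` has columns (cancer, gene, direction[, z_high]).  With
    ``mode="significant"`` (default) only genes classified oncogenic or
    protective contribute; a cancer whose signature is entirely neutral is an
    error.  With ``mode="signed"`` every gene contributes with the sign of its
    survival statistic (``z_high``), regardless of significance.

    Returns a table (sample, cancer_type, score, n_oncogenic, n_protective).
    """
    if mode not in ("significant", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    cancer_labels = cancer_labels.reindex(norm_expr.columns)
    records = []
    for cancer, cols in norm_expr.columns.to_series().groupby(cancer_labels, sort=False):
        cols = list(cols)
        sub = directions[directions["cancer"] == cancer]
        if sub.empty:
            raise ValueError(f"no directions available for cancer {cancer!r}")
        if mode == "signed":
            zh = sub.set_index("gene")["z_high"]
            onc = list(zh.index[zh > 0])
            prot = list(zh.index[zh < 0])
        else:
            onc = list(sub.loc[sub["direction"] == DIRECTION_ONCOGENIC, "gene"])
            prot = list(sub.loc[sub["direction"] == DIRECTION_PROTECTIVE, "gene"])
        if not onc and not prot:
            raise ValueError(f"signature empty for cancer {cancer!r}: all genes neutral")
        onc = [g for g in onc if g in norm_expr.index]
        prot = [g for g in prot if g in norm_expr.index]
        score = np.zeros(len(cols))
        if onc:
            score = score + norm_expr.loc[onc, cols].to_numpy().sum(axis=0)
        if prot:
            score = score - norm_expr.loc[prot, cols].to_numpy().sum(axis=0)
        for s, v in zip(cols, score):
            records.append(
                {
                    "sample": s,
                    "cancer_type": cancer,
                    "score": float(v),
                    "n_oncogenic": len(onc),
                    "n_protective": len(prot),
                }
            )
    return pd.DataFrame(records)


@dataclass
class StratificationResult:
    """Score-high vs score-low split of one cancer cohort."""

    strata: pd.Series  # sample -> "high" / "low"
    cutpoint: CutpointResult
    logrank_p: float
    logrank_z_high: float  # > 0: high stratum worse survival
    km_high: KaplanMeierEstimate
    km_low: KaplanMeierEstimate

    @property
    def high_worse(self) -> bool:
        return self.logrank_z_high > 0


def stratify_by_score(
    scores: pd.Series,
    time,
    event,
    minprop: float = 0.1,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> StratificationResult:
    """Split samples at the score's optimal cutpoint and compare survival.

    ``scores`` is indexed by sample and aligned positionally with ``time`` /
    ``event``.  The permutation p of the cutpoint scan is in ``.cutpoint.p``;
    ``logrank_p`` is the (naive) log-rank p of the realized split.
    """
    values = scores.to_numpy(float)
    cut = max_rank_cutpoint(
        values, time, event, minprop=minprop, n_perm=n_perm, seed=seed, rng=rng
    )
    high = values > cut.cutpoint
    strata = pd.Series(np.where(high, "high", "low"), index=scores.index, name="stratum")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    lr = logrank_test(time[high], event[high], time[~high], event[~high])
    return StratificationResult(
        strata=strata,
        cutpoint=cut,
        logrank_p=lr.p,
        logrank_z_high=lr.z,
        km_high=km_estimate(time[high], event[high]),
        km_low=km_estimate(time[~high], event[~high]),
    )


def signature_activity(norm_expr: pd.DataFrame, gene_set: list[str], name: str = "") -> pd.Series:
    """Per-sample activity of a gene set: mean z across the set's present genes.

    A deliberately simple stand-in for sample-level set activity scoring; on
    z-scored input it is the set's average normalized expression.
    """
    present = [g for g in dict.fromkeys(gene_set) if g in norm_expr.index]
    if not present:
        raise ValueError(f"no gene of set {name or gene_set!r} present in the matrix")
    missing = len(set(gene_set)) - len(present)
    if missing:
        logger.info("signature %s: %d gene(s) absent from matrix", name or "<set>", missing)
    return norm_expr.loc[present].mean(axis=0)
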