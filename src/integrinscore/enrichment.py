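"""Fold-change ranking, pre-ranked GSEA, multiple-testing adjustment, group
tests, and score-vs-feature association (immune features, drugs, ICB response).

The DEG step is deliberately simple: genes are ranked by the log2 ratio of
pseudocounted stratum means on the TPM scale, with rank-sum p-values and BH
adjustment supplying the DEG flags.  Downstream GSEA consumes only the ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .regulome import passes_correlation_filter, spearman
from .scoring import stratify_by_score

logger = logging.getLogger("integrinscore")

__all__ = [
    "rank_genes_by_fold_change",
    "gsea_preranked",
    "enrichment_score",
    "bh_adjust",
    "group_compare",
    "score_feature_correlation",
    "select_cmap_compounds",
    "icb_response_summary",
]


def rank_genes_by_fold_change(
    expr: pd.DataFrame,
    strata: pd.Series,
    pseudocount: float = 1.0,
    deg_abs_log2fc: float = 1.0,
    deg_fdr: float = 0.05,
) -> pd.DataFrame:
    """Rank all genes by high-vs-low stratum fold change.

    Metric: log2((mean_high + c) / (mean_low + c)) on the TPM scale with
    pseudocount ``c``.  Rank-sum (two-sided) p-values with BH adjustment give
    the DEG flag at |log2FC| >= ``deg_abs_log2fc`` and q < ``deg_fdr``.  The
    result is sorted by descending metric, ties broken by gene identifier.
    """
    strata = strata.reindex(expr.columns)
    high = list(expr.columns[(strata == "high").to_numpy()])
    low = list(expr.columns[(strata == "low").to_numpy()])
    if len(high) < 3 or len(low) < 3:
        raise ValueError(f"each stratum needs >= 3 samples, got {len(high)}/{len(low)}")
    hi = expr[high].to_numpy(float)
    lo = expr[low].to_numpy(float)
    log2fc = np.log2((hi.mean(axis=1) + pseudocount) / (lo.mean(axis=1) + pseudocount))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes yield exact-tie warnings
        res = stats.mannwhitneyu(hi, lo, axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, float)
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene": expr.index,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "deg": (np.abs(log2fc) >= deg_abs_log2fc) & (q < deg_fdr),
        }
    )
    return out.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------

def enrichment_score(metric: np.ndarray, hit: np.ndarray, weight: float = 1.0):
    """Running-sum enrichment score of one gene set against a ranked list.

    Hits increment by |metric|^weight (normalized to sum 1 over hits); misses
    decrement by 1/(N - n_set).  Returns (ES, extremum position, running sum).
    """
    n = metric.size
    nh = int(hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("set must hit a strict subset of the ranked list")
    w = np.abs(metric) ** weight
    wh = np.where(hit, w, 0.0)
    total = wh.sum()
    if total <= 0:  # all hit metrics zero (possible at weight > 0): fall back to equal steps
        wh = hit.astype(float)
        total = float(nh)
    step = wh / total - (~hit) / float(n - nh)
    running = np.cumsum(step)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), pos, running


def _null_es(metric, hit_count, n_perm, weight, rng):
    n = metric.size
    out = np.empty(n_perm)
    for i in range(n_perm):
        hit = np.zeros(n, dtype=bool)
        hit[rng.choice(n, size=hit_count, replace=False)] = True
        out[i], _, _ = enrichment_score(metric, hit, weight)
    return out


def gsea_preranked(
    ranked: pd.DataFrame | pd.Series,
    sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = 0,
    min_size: int = 5,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a collection of gene sets.

    ``ranked`` is a Series (gene -> metric) or the frame from
    :func:`rank_genes_by_fold_change`; it must be in descending metric order.
    The null is by gene-label permutation (random sets of the same size),
    NES = ES / mean |null ES| of the same sign, and the FDR q follows the
    standard same-sign null-ratio procedure over the pooled normalized null.
    """
    if isinstance(ranked, pd.DataFrame):
        ranked = ranked.set_index("gene")["log2fc"]
    genes = np.asarray(ranked.index)
    metric = ranked.to_numpy(float)
    if genes.size < 15:
        raise ValueError("ranked list must contain at least 15 genes")
    if pd.Index(genes).duplicated().any():
        raise ValueError("ranked list contains duplicate genes")
    if not np.all(np.diff(metric) <= 1e-12):
        raise ValueError("ranked list must be sorted by descending metric")
    pos_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows, null_norm_pool, obs_nes = [], [], []
    for name, members in sets.items():
        present = [g for g in dict.fromkeys(members) if g in pos_of]
        if len(present) < min_size:
            warnings.warn(f"set {name!r}: {len(present)} gene(s) in list (< {min_size}); skipped")
            continue
        if len(present) == genes.size:
            warnings.warn(f"set {name!r} covers the whole ranked list; skipped")
            continue
        hit = np.zeros(genes.size, dtype=bool)
        hit[[pos_of[g] for g in present]] = True
        es, pos, _ = enrichment_score(metric, hit, weight)
        null = _null_es(metric, len(present), n_perm, weight, rng)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if same.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size) if same.size else 1.0
        if es >= 0:
            leading = [g for g in genes[: pos + 1] if hit[pos_of[g]]]
        else:
            leading = [g for g in genes[pos:] if hit[pos_of[g]]]
        with np.errstate(invalid="ignore", divide="ignore"):
            null_norm = np.where(
                null >= 0,
                null / (np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan),
                null / (np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan),
            )
        null_norm_pool.append(null_norm[np.isfinite(null_norm)])
        obs_nes.append(nes)
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "p": float(p),
                "size_used": len(present),
                "leading_edge": ",".join(leading),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set", "es", "nes", "p", "q", "significant", "size_used", "leading_edge"]
        )
    pool = np.concatenate(null_norm_pool)
    nes_arr = np.asarray(obs_nes, float)
    q = np.full(nes_arr.size, np.nan)
    for i, v in enumerate(nes_arr):
        if not np.isfinite(v):
            q[i] = 1.0
            continue
        if v >= 0:
            null_frac = (pool >= v).mean()
            obs_frac = (nes_arr[np.isfinite(nes_arr)] >= v).mean()
        else:
            null_frac = (pool <= v).mean()
            obs_frac = (nes_arr[np.isfinite(nes_arr)] <= v).mean()
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    out = pd.DataFrame(rows)
    out.insert(4, "q", q)
    out.insert(5, "significant", out["q"] < fdr_threshold)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_compare(values=None, labels=None, test: str = "wilcoxon", table=None):
    """Dispatch the published two-group / multi-group / categorical tests.

    Continuous: ``test`` in {"t", "wilcoxon", "kruskal"} with ``values`` and
    group ``labels`` (Wilcoxon = two-sided rank-sum with normal approximation,
    tie and continuity correction; t = Student's equal-variance).  Categorical:
    {"chi2", "fisher"} with a contingency ``table`` (Fisher requires 2x2;
    chi-square is Pearson without Yates correction).  Returns (statistic, p).
    """
    if test in ("chi2", "fisher"):
        if table is None:
            raise ValueError(f"test {test!r} requires a contingency table")
        table = np.asarray(table)
        if test == "fisher":
            if table.shape != (2, 2):
                raise ValueError(f"fisher requires a 2x2 table, got shape {table.shape}")
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            return float(odds), float(p)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)

    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    if test == "t":
        if len(groups) != 2:
            raise ValueError("t-test requires exactly two groups")
        s, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
    elif test == "wilcoxon":
        if len(groups) != 2:
            raise ValueError("wilcoxon requires exactly two groups")
        s, p = stats.mannwhitneyu(
            groups[0], groups[1], alternative="two-sided", method="asymptotic"
        )
    elif test == "kruskal":
        s, p = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(s), float(p)


# ---------------------------------------------------------------------------
# score-vs-feature association
# ---------------------------------------------------------------------------

def score_feature_correlation(
    scores: pd.DataFrame,
    feature_table: pd.DataFrame,
    mode: str = "immune",
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-cancer Spearman between the signature score and each feature.

    ``scores`` has columns (sample, cancer_type, score); ``feature_table`` is
    features x samples.  ``mode`` sets the flagging rule: "drug" applies
    |rho| >= drug_rho and p < drug_p and labels compounds "resistant" (rho > 0)
    or "sensitive" (rho < 0); other modes flag at p < survival_alpha only.
    """
    config = config or RunConfig()
    rows = []
    by_sample = scores.set_index("sample")
    shared = [s for s in feature_table.columns if s in by_sample.index]
    for cancer in sorted(by_sample.loc[shared, "cancer_type"].unique()):
        cols = [s for s in shared if by_sample.loc[s, "cancer_type"] == cancer]
        sv = by_sample.loc[cols, "score"].to_numpy(float)
        for feature in feature_table.index:
            fv = feature_table.loc[feature, cols].to_numpy(float)
            ok = np.isfinite(fv) & np.isfinite(sv)
            if ok.sum() < 3:
                warnings.warn(f"{feature} in {cancer}: fewer than 3 matched samples; skipped")
                continue
            try:
                rho, p, n = spearman(sv[ok], fv[ok])
            except ValueError:
                warnings.warn(f"{feature} in {cancer}: degenerate values; skipped")
                continue
            if mode == "drug":
                sig = passes_correlation_filter(rho, p, config.drug_rho, config.drug_p)
                direction = "" if not sig else ("resistant" if rho > 0 else "sensitive")
            else:
                sig = p < config.survival_alpha
                direction = "positive" if rho > 0 else "negative"
            rows.append(
                {
                    "cancer": cancer,
                    "feature": feature,
                    "mode": mode,
                    "statistic_kind": "spearman",
                    "rho": rho,
                    "p": p,
                    "n": n,
                    "significant": sig,
                    "direction": direction,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cancer", "feature", "mode", "statistic_kind", "rho", "p", "n",
                 "significant", "direction"],
    )


def select_cmap_compounds(
    es_table: pd.DataFrame,
    threshold: float = 95.0,
    min_cancers: int = 10,
) -> pd.DataFrame:
    """Compound selection on a provided enrichment-score table (compounds x cancers).

    A compound is "positive" when its score exceeds +threshold in at least
    ``min_cancers`` cancer types, "negative" when below -threshold in at least
    that many; others are dropped.
    """
    pos = (es_table > threshold).sum(axis=1)
    neg = (es_table < -threshold).sum(axis=1)
    rows = []
    for compound in es_table.index:
        if pos[compound] >= min_cancers:
            rows.append({"compound": compound, "direction": "positive",
                         "n_cancers": int(pos[compound])})
        elif neg[compound] >= min_cancers:
            rows.append({"compound": compound, "direction": "negative",
                         "n_cancers": int(neg[compound])})
    return pd.DataFrame(rows, columns=["compound", "direction", "n_cancers"])


@dataclass
class IcbSummary:
    strata: pd.Series
    rate_high: float
    rate_low: float
    fisher_p: float
    logrank_p: float | None


def icb_response_summary(
    scores: pd.Series,
    response: pd.Series,
    time=None,
    event=None,
    minprop: float = 0.1,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> IcbSummary:
    """Score-stratified ICB responder rates with a Fisher exact comparison.

    Stratifies at the score's optimal survival-free cutpoint when survival is
    given (the cutpoint needs time/event); without survival, the median split
    is used.  Responder rate per stratum plus the two-sided Fisher p on the
    2x2 responder-by-stratum table; log-rank p between strata when survival is
    supplied.
    """
    response = response.reindex(scores.index)
    bad = ~response.isin(["responder", "non-responder"])
    if bad.any():
        raise ValueError(f"unknown response label(s): {sorted(response[bad].unique())}")
    logrank_p = None
    if time is not None and event is not None:
        strat = stratify_by_score(
            scores, time, event, minprop=minprop, n_perm=n_perm, seed=seed
        )
        strata = strat.strata
        logrank_p = strat.logrank_p
    else:
        med = scores.median()
        high = scores > med
        if high.all() or not high.any():
            raise ValueError("degenerate covariate: median split yields a single stratum")
        strata = pd.Series(np.where(high, "high", "low"), index=scores.index, name="stratum")
    tab = np.zeros((2, 2), dtype=int)
    for i, stratum in enumerate(("high", "low")):
        in_s = strata == stratum
        tab[i, 0] = int(((response == "responder") & in_s).sum())
        tab[i, 1] = int(((response == "non-responder") & in_s).sum())
    if tab.sum(axis=1).min() == 0:
        raise ValueError("a stratum is empty; cannot summarize response")
    _, fisher_p = stats.fisher_exact(tab, alternative="two-sided")
    rate_high = tab[0, 0] / tab[0].sum()
    rate_low = tab[1, 0] / tab[1].sum()
    return IcbSummary(
        strata=strata,
        rate_high=float(rate_high),
        rate_low=float(rate_low),
        fisher_p=float(fisher_p),
        logrank_p=logrank_p,
    )
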