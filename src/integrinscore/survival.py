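"""Survival machinery: Kaplan-Meier estimation, the log-rank test, maximally
selected rank-statistic cutpoints, and per-gene survival-direction assignment.

The optimal-cutpoint procedure scans every distinct expression value as a
candidate threshold (subject to a minimum group proportion on both sides),
computes the standardized log-rank statistic of the resulting two-group split,
and keeps the threshold maximising |z|.  Because the maximum over many data-
driven splits is optimistic, significance is assessed by permutation: the
expression values are permuted against the (time, event) pairs and the scan is
re-maximised for each permutation, giving an exact p-value under exchangeability.

A gene is *oncogenic* in a cancer when its high-expression stratum at the optimal
cutpoint has significantly worse survival, *protective* when significantly better,
and *neutral* otherwise (p >= alpha or degenerate expression).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

logger = logging.getLogger("integrinscore")

__all__ = [
    "KaplanMeierEstimate",
    "LogrankResult",
    "CutpointResult",
    "km_estimate",
    "logrank_test",
    "max_rank_cutpoint",
    "assign_gene_direction",
    "assign_directions",
    "DIRECTION_ONCOGENIC",
    "DIRECTION_PROTECTIVE",
    "DIRECTION_NEUTRAL",
]

DIRECTION_ONCOGENIC = "oncogenic"
DIRECTION_PROTECTIVE = "protective"
DIRECTION_NEUTRAL = "neutral"


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierEstimate:
    """Product-limit estimate: right-continuous non-increasing step function.

    ``times`` are the distinct event times (steps); ``survival`` the value of
    S(t) at and after each step.  S(0) = 1; censored-only times create no steps.
    """

    times: np.ndarray
    survival: np.ndarray
    n: int
    n_events: int

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[1.0], self.survival])
        return vals[idx]


def km_estimate(time, event) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimator (delegates to lifelines)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("km_estimate requires at least one sample")
    if (time < 0).any() or not np.isfinite(time).all():
        raise ValueError("times must be finite and non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_.iloc[:, 0]
    # keep only times where the estimate actually drops (event times)
    vals = sf.to_numpy()
    ts = sf.index.to_numpy(dtype=float)
    prev = np.concatenate([[1.0], vals[:-1]])
    drop = vals < prev - 1e-15
    return KaplanMeierEstimate(
        times=ts[drop], survival=vals[drop], n=time.size, n_events=int(event.sum())
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    statistic: float  # chi-square, df = 1
    z: float  # signed: > 0 when group A has more events than expected
    p: float
    n_events: int


def _event_grid(time: np.ndarray, event: np.ndarray):
    """Distinct event times with total deaths d_j and numbers at risk n_j."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ev_times = np.unique(t[e == 1])
    # at risk: number with time >= t_j
    n_at_risk = t.size - np.searchsorted(t, ev_times, side="left")
    d = np.array([int(e[t == tj].sum()) for tj in ev_times])
    return ev_times, d, n_at_risk


class _LogrankScan:
    """Shared quantities for log-rank statistics over sample subgroups.

    For a subgroup A, with C_j = number at risk in A at event time t_j:
      O_A - E_A = sum_j (d_Aj - d_j * C_j / n_j)
      Var       = sum_j d_j (n_j - d_j) / (n_j - 1) * (C_j/n_j) (1 - C_j/n_j)
    The matrix ``R`` (event times x samples) of at-risk indicators lets both be
    computed for *all* prefix groups of an ordering in one cumulative sum, which
    is what makes the cutpoint scan and its permutations cheap.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        self.time = time
        self.event = event.astype(float)
        self.ev_times, self.d, self.n_risk = _event_grid(time, event)
        if self.ev_times.size == 0:
            raise ValueError("no events")
        # R[j, i] = sample i at risk at event time j
        self.R = (time[None, :] >= self.ev_times[:, None]).astype(float)
        # deaths per sample-time cell: d_Aj summed = events in A (events counted once)
        n, d = self.n_risk.astype(float), self.d.astype(float)
        self.rate = d / n  # d_j / n_j
        with np.errstate(divide="ignore", invalid="ignore"):
            w = d * (n - d) / np.where(n > 1, n - 1, np.nan)
        w = np.where(np.isfinite(w), w, 0.0)
        self.var_a = w / n  # multiplies C_j
        self.var_b = w / (n * n)  # multiplies C_j^2

    def prefix_stats(self, order: np.ndarray):
        """(O - E)(m) and Var(m) for prefix groups of the given sample order."""
        C = np.cumsum(self.R[:, order], axis=1)
        O = np.cumsum(self.event[order])
        E = self.rate @ C
        V = self.var_a @ C - self.var_b @ (C * C)
        return O - E, V

    def group_stats(self, mask: np.ndarray):
        """(O - E, Var) for the subgroup flagged by ``mask``."""
        C = self.R[:, mask].sum(axis=1)
        O = self.event[mask].sum()
        E = float(self.rate @ C)
        V = float(self.var_a @ C - self.var_b @ (C * C))
        return O - E, V


def logrank_test(time_a, event_a, time_b, event_b) -> LogrankResult:
    """Two-group log-rank test with hypergeometric variance.

    The signed z is positive when group A has more observed events than expected
    (i.e. worse survival than group B).
    """
    time_a = np.asarray(time_a, float)
    time_b = np.asarray(time_b, float)
    event_a = np.asarray(event_a, int)
    event_b = np.asarray(event_b, int)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("each group needs at least one sample")
    time = np.concatenate([time_a, time_b])
    event = np.concatenate([event_a, event_b])
    if event.sum() == 0:
        raise ValueError("no events")
    scan = _LogrankScan(time, event)
    mask = np.zeros(time.size, dtype=bool)
    mask[: time_a.size] = True
    o_minus_e, var = scan.group_stats(mask)
    if var <= 0:
        raise ValueError("zero variance: groups are structurally degenerate")
    z = o_minus_e / np.sqrt(var)
    statistic = z * z
    return LogrankResult(
        statistic=float(statistic),
        z=float(z),
        p=float(stats.chi2.sf(statistic, df=1)),
        n_events=int(event.sum()),
    )


# ---------------------------------------------------------------------------
# maximally selected rank statistic
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    """Optimal cutpoint on a continuous covariate against survival.

    ``cutpoint`` is the largest covariate value assigned to the *low* group
    (low: value <= cutpoint).  ``statistic`` is max |z| over admissible
    thresholds; ``z_high`` is the signed log-rank z of the high group at the
    selected threshold (> 0: high group has worse survival).  ``p`` is the
    permutation p-value; ``naive_p`` the chi-square p of the selected split,
    uncorrected for the threshold search.
    """

    cutpoint: float
    statistic: float
    z_high: float
    p: float
    naive_p: float
    n_high: int
    n_low: int
    direction_of_risk: str  # "high" or "low": which stratum has worse survival


def _scan_max(scan: _LogrankScan, order: np.ndarray, valid: np.ndarray):
    """max |z| over admissible prefix thresholds, with the argmax position."""
    o_minus_e, var = scan.prefix_stats(order)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = o_minus_e / np.sqrt(var)
    z = np.where(valid & (var > 1e-12), z, np.nan)
    if np.isnan(z).all():
        return np.nan, -1, np.nan
    absz = np.abs(z)
    m = int(np.nanargmax(absz))  # first index on ties -> smallest cutpoint
    return float(absz[m]), m, float(z[m])


def max_rank_cutpoint(
    values,
    time,
    event,
    minprop: float = 0.1,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CutpointResult:
    """Optimal survival cutpoint by the maximally selected log-rank statistic.

    Every distinct value of ``values`` is tried as a threshold provided both
    resulting groups hold at least ``minprop`` of the samples; ties in the
    maximal statistic resolve to the smallest cutpoint.  The p-value comes from
    ``n_perm`` permutations of the covariate against the (time, event) pairs,
    each re-maximised over thresholds: p = (1 + #{perm max >= observed}) / (1 + n_perm).
    """
    values = np.asarray(values, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = values.size
    if n != time.size or n != event.size:
        raise ValueError("values, time and event must have equal length")
    if n < 2 / minprop:
        raise ValueError(f"need at least {int(np.ceil(2 / minprop))} samples at minprop={minprop}")
    if np.ptp(values) == 0:
        raise ValueError("degenerate covariate: all values equal")
    if rng is None:
        rng = np.random.default_rng(seed)

    order = np.argsort(values, kind="stable")
    x_sorted = values[order]
    # admissible prefix sizes m (low group = m smallest values): threshold must fall
    # between distinct values and respect minprop on both sides
    m = np.arange(1, n + 1)
    distinct = np.empty(n, dtype=bool)
    distinct[:-1] = x_sorted[:-1] < x_sorted[1:]
    distinct[-1] = False  # full set is not a split
    valid = distinct & (m / n >= minprop) & ((n - m) / n >= minprop)
    if not valid.any():
        raise ValueError("no threshold satisfies the minimum group proportion")

    scan = _LogrankScan(time, event)
    obs_stat, obs_m, obs_z_low = _scan_max(scan, order, valid)
    if not np.isfinite(obs_stat):
        raise ValueError("zero variance at every admissible threshold")

    exceed = 0
    for _ in range(n_perm):
        perm_stat, _, _ = _scan_max(scan, rng.permutation(n), valid)
        if np.isfinite(perm_stat) and perm_stat >= obs_stat:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)

    cutpoint = float(x_sorted[obs_m])
    n_low = obs_m + 1
    n_high = n - n_low
    z_high = -obs_z_low  # prefix stats are for the low group
    naive_p = float(stats.chi2.sf(obs_stat**2, df=1))
    return CutpointResult(
        cutpoint=cutpoint,
        statistic=obs_stat,
        z_high=float(z_high),
        p=float(p),
        naive_p=naive_p,
        n_high=int(n_high),
        n_low=int(n_low),
        direction_of_risk="high" if z_high > 0 else "low",
    )


# ---------------------------------------------------------------------------
# direction assignment
# ---------------------------------------------------------------------------

def assign_gene_direction(
    gene: str,
    expr_values,
    time,
    event,
    *,
    cancer: str = "",
    endpoint: str = "OS",
    alpha: float = 0.05,
    minprop: float = 0.1,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict:
    """Classify one gene as oncogenic / protective / neutral in one cancer.

    Runs the optimal-cutpoint scan on the configured endpoint; with permutation
    p < ``alpha`` the gene is oncogenic when the high-expression stratum has
    worse survival and protective otherwise, else neutral.  Genes with
    (near-)constant expression, or too few distinct values to admit a cutpoint,
    are classified neutral with a warning rather than aborting a cohort run.
    """
    expr_values = np.asarray(expr_values, float)
    row = {
        "cancer": cancer,
        "gene": gene,
        "direction": DIRECTION_NEUTRAL,
        "cutpoint": np.nan,
        "statistic": np.nan,
        "z_high": np.nan,
        "p": np.nan,
        "naive_p": np.nan,
        "endpoint": endpoint,
        "n": int(expr_values.size),
    }
    n_distinct = np.unique(expr_values).size
    if np.var(expr_values) < 1e-12 or n_distinct < 2 / minprop:
        warnings.warn(
            f"gene {gene!r} in {cancer!r}: near-constant expression "
            f"({n_distinct} distinct values); classified neutral",
            stacklevel=2,
        )
        return row
    try:
        cut = max_rank_cutpoint(
            expr_values, time, event, minprop=minprop, n_perm=n_perm, rng=rng, seed=seed
        )
    except ValueError as err:
        warnings.warn(
            f"gene {gene!r} in {cancer!r}: cutpoint scan failed ({err}); classified neutral",
            stacklevel=2,
        )
        return row
    row.update(
        cutpoint=cut.cutpoint,
        statistic=cut.statistic,
        z_high=cut.z_high,
        p=cut.p,
        naive_p=cut.naive_p,
    )
    if cut.p < alpha:
        row["direction"] = (
            DIRECTION_ONCOGENIC if cut.direction_of_risk == "high" else DIRECTION_PROTECTIVE
        )
    return row


def assign_directions(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    genes=None,
    *,
    endpoint_for=None,
    alpha: float = 0.05,
    minprop: float = 0.1,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-cancer, per-gene direction table over a multi-cancer cohort.

    ``expression`` is genes x samples (TPM scale); ``clinical`` must carry
    sample, cancer_type and the endpoint columns.  Samples missing the
    configured endpoint are dropped per cancer with a logged count.
    """
    if genes is None:
        genes = list(expression.index)
    if endpoint_for is None:
        endpoint_for = lambda cancer: "OS"  # noqa: E731
    rng = np.random.default_rng(seed)
    rows = []
    for cancer, sub in clinical.groupby("cancer_type", sort=True):
        endpoint = endpoint_for(cancer)
        tcol, ecol = f"{endpoint.lower()}_time", f"{endpoint.lower()}_event"
        keep = sub.dropna(subset=[tcol, ecol])
        dropped = len(sub) - len(keep)
        if dropped:
            logger.info("%s: dropped %d samples lacking %s", cancer, dropped, endpoint)
        samples = [s for s in keep["sample"] if s in expression.columns]
        keep = keep.set_index("sample").loc[samples]
        time = keep[tcol].to_numpy(float)
        event = keep[ecol].to_numpy(int)
        for gene in genes:
            rows.append(
                assign_gene_direction(
                    gene,
                    expression.loc[gene, samples].to_numpy(float),
                    time,
                    event,
                    cancer=cancer,
                    endpoint=endpoint,
                    alpha=alpha,
                    minprop=minprop,
                    n_perm=n_perm,
                    rng=rng,
                )
            )
    return pd.DataFrame(rows)
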