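"""Model/Results facade over the signature pipeline.

``IntegrinSignatureModel`` is constructed from an expression matrix and a
clinical table; ``fit()`` assigns per-cancer survival directions to the
signature genes, computes the per-sample score, and stratifies each cancer at
the score's optimal cutpoint.  The returned ``IntegrinSignatureResults`` holds
the direction table, score table and per-cancer stratification, and offers a
``summary()`` table and Kaplan-Meier plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as iio
from .config import RunConfig
from .scoring import (
    StratificationResult,
    compute_integrin_score,
    normalize_expression,
    stratify_by_score,
)
from .simulate import INTEGRIN_GENES
from .survival import assign_directions

__all__ = ["IntegrinSignatureModel", "IntegrinSignatureResults"]


class IntegrinSignatureModel:
    """Survival-weighted signature scoring model for a multi-cancer cohort.

    Parameters
    ----------
    expression : genes x samples TPM-scale matrix.
    clinical : table with sample, cancer_type and os/pfs endpoint columns.
    genes : signature genes to score (default: the 26 integrin subunit genes
        present in the matrix).
    config : run configuration (endpoints, thresholds, permutation counts).
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        clinical: pd.DataFrame,
        genes: list[str] | None = None,
        config: RunConfig | None = None,
    ):
        self.config = config or RunConfig()
        if genes is None:
            genes = [g for g in INTEGRIN_GENES if g in expression.index]
            if not genes:
                raise ValueError(
                    "no integrin subunit gene found in the matrix; pass genes= explicitly"
                )
        missing = [g for g in genes if g not in expression.index]
        if missing:
            raise ValueError(f"signature gene(s) absent from expression matrix: {missing}")
        shared = [s for s in expression.columns if s in set(clinical["sample"])]
        if len(shared) < expression.shape[1]:
            dropped = expression.shape[1] - len(shared)
            import logging

            logging.getLogger("integrinscore").info(
                "%d expression sample(s) without clinical data dropped", dropped
            )
        self.expression = expression[shared]
        self.clinical = clinical[clinical["sample"].isin(shared)].reset_index(drop=True)
        self.genes = list(genes)
        self.cancer_labels = self.clinical.set_index("sample")["cancer_type"].reindex(shared)

    @classmethod
    def from_tsv(cls, expression_path, clinical_path, **kwargs) -> "IntegrinSignatureModel":
        return cls(
            iio.read_matrix_tsv(expression_path),
            iio.read_clinical_tsv(clinical_path),
            **kwargs,
        )

    def fit(
        self, seed: int | None = None, score_mode: str = "significant"
    ) -> "IntegrinSignatureResults":
        """Assign directions, score every sample, stratify every cancer.

        ``score_mode="signed"`` forces every gene into the score with the sign
        of its survival statistic regardless of significance.
        """
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        directions = assign_directions(
            self.expression,
            self.clinical,
            self.genes,
            endpoint_for=cfg.endpoint_for,
            alpha=cfg.survival_alpha,
            minprop=cfg.minprop,
            n_perm=cfg.n_perm_cutpoint,
            seed=seed,
        )
        norm = normalize_expression(self.expression, self.cancer_labels)
        scores = compute_integrin_score(norm, directions, self.cancer_labels, mode=score_mode)
        rng = np.random.default_rng(None if seed is None else seed + 1)
        stratifications: dict[str, StratificationResult] = {}
        clin = self.clinical.set_index("sample")
        strata_col = pd.Series("", index=scores["sample"], dtype=object)
        for cancer, sub in scores.groupby("cancer_type", sort=True):
            ep = cfg.endpoint_for(cancer).lower()
            rows = clin.loc[sub["sample"]]
            keep = rows[f"{ep}_time"].notna() & rows[f"{ep}_event"].notna()
            s = sub.set_index("sample")["score"][keep.to_numpy()]
            strat = stratify_by_score(
                s,
                rows.loc[keep, f"{ep}_time"].to_numpy(float),
                rows.loc[keep, f"{ep}_event"].to_numpy(int),
                minprop=cfg.minprop,
                n_perm=cfg.n_perm_cutpoint,
                rng=rng,
            )
            stratifications[cancer] = strat
            strata_col.loc[strat.strata.index] = strat.strata
        scores = scores.assign(stratum=strata_col.to_numpy())
        return IntegrinSignatureResults(
            model=self,
            directions=directions,
            normalized=norm,
            scores=scores,
            stratifications=stratifications,
        )


@dataclass
class IntegrinSignatureResults:
    """Fitted signature: directions, scores, strata and per-cancer survival splits."""

    model: IntegrinSignatureModel
    directions: pd.DataFrame
    normalized: pd.DataFrame
    scores: pd.DataFrame
    stratifications: dict[str, StratificationResult] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """One row per cancer: signature composition and stratification outcome."""
        rows = []
        for cancer, strat in self.stratifications.items():
            sub = self.directions[self.directions["cancer"] == cancer]
            rows.append(
                {
                    "cancer": cancer,
                    "endpoint": sub["endpoint"].iloc[0] if len(sub) else "",
                    "n": int((self.scores["cancer_type"] == cancer).sum()),
                    "n_oncogenic": int((sub["direction"] == "oncogenic").sum()),
                    "n_protective": int((sub["direction"] == "protective").sum()),
                    "n_neutral": int((sub["direction"] == "neutral").sum()),
                    "score_cutpoint": strat.cutpoint.cutpoint,
                    "cutpoint_perm_p": strat.cutpoint.p,
                    "logrank_p": strat.logrank_p,
                    "high_worse": strat.high_worse,
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        return (
            "Integrin signature fit\n"
            f"  genes: {len(self.model.genes)}, cancers: {len(self.stratifications)}\n"
            + self.summary().to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )

    def plot_km(self, cancer: str, ax=None):
        """Kaplan-Meier curves of the score-high vs score-low strata."""
        import matplotlib.pyplot as plt

        strat = self.stratifications[cancer]
        if ax is None:
            _, ax = plt.subplots()
        for km, label, color in (
            (strat.km_high, "score high", "#c0392b"),
            (strat.km_low, "score low", "#2980b9"),
        ):
            t = np.concatenate([[0.0], np.repeat(km.times, 2)])
            s = np.concatenate([[1.0, 1.0], np.repeat(km.survival, 2)[:-1]])
            ax.plot(t, s, label=label, color=color)
        ax.set_xlabel("time (days)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.set_title(f"{cancer}: log-rank p = {strat.logrank_p:.3g}")
        ax.legend()
        return ax

    def write(self, outdir) -> None:
        """Write directions and scores as TSV to a directory."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        iio.write_table_tsv(self.directions, outdir / "directions.tsv")
        iio.write_table_tsv(self.scores, outdir / "scores.tsv")
        iio.write_table_tsv(self.summary(), outdir / "summary.tsv")
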