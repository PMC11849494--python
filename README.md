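# integrinscore

Survival-weighted integrin signature scoring and multi-omic correlation
screens for multi-cancer expression cohorts.

Integrins — the 26 human α/β subunit genes whose heterodimers couple cells to
the extracellular matrix — are dysregulated across most cancers, but in a
strongly cancer-dependent way: the same gene can predict shorter survival in
one tumor type and longer survival in another. This package implements a
pan-cancer analysis pipeline built around that observation, for computational
biologists who want to score a signature whose gene weights are *learned from
survival* per cancer type rather than fixed globally:

1. **Direction assignment.** Per cancer and per signature gene, patients are
   split at the optimal expression cutpoint (maximally selected rank
   statistic: the threshold maximising the standardized log-rank |z|, with a
   permutation p-value that accounts for the threshold search). A gene is
   *oncogenic* when its high-expression stratum has significantly worse
   survival (p < 0.05), *protective* when better, *neutral* otherwise.
2. **Scoring.** With z the within-cancer z-score of log2(TPM+1),

       score_i = Σ_{g ∈ oncogenic} z_gi − Σ_{g ∈ protective} z_gi .

3. **Stratification.** Each cancer is split into score-high/low groups at the
   score's own optimal cutpoint and the strata compared by log-rank and
   Kaplan–Meier curves.
4. **Mechanism and association screens.** Consensus clustering (Monti
   resampling, k-means base) on the signature transcriptome; promoter-probe
   methylation mapping (TSS −1000..+200 bp, highest mean β probe) and layered
   Spearman screens for methylation (|ρ| ≥ 0.15, p < 0.05), miRNAs
   (expression filter, |ρ| ≥ 0.3 & p < 0.05 in > 5 cancers, validated-pair
   intersection) and TFs (|ρ| ≥ 0.2, p < 0.01, top-10 by signature targets);
   CNV–expression association; fold-change ranking with pre-ranked GSEA
   (FDR < 0.1); and score-vs-feature association for immune features, drug
   IC50 values (|ρ| ≥ 0.1 & p < 0.05, resistant/sensitive labels) and ICB
   response.

Everything runs on plain TSV/GMT/BED inputs, and a first-class synthetic
cohort generator (`integrinscore.simulate`) produces multi-cancer cohorts
with planted, recoverable ground truth — Weibull proportional-hazards
survival with per-gene log-hazard coefficients, copula-coupled omics layers,
planted clusters, CNV shifts and score-correlated features — so every stage
of the pipeline is testable end to end. See `docs/methods.md` for the full
statistical description.

## Worked example

```python
from integrinscore import (
    IntegrinSignatureModel, RunConfig, SimConfig, simulate_cohort,
)

cohort, truth = simulate_cohort(SimConfig(n_cancers=2, samples_per_cancer=200, seed=7))
model = IntegrinSignatureModel(cohort.expression, cohort.clinical,
                               config=RunConfig(seed=7, n_perm_cutpoint=199))
fit = model.fit()
print(fit)
```

```
Integrin signature fit
  genes: 26, cancers: 2
cancer endpoint   n  n_oncogenic  n_protective  n_neutral  score_cutpoint  cutpoint_perm_p  logrank_p  high_worse
   C01       OS 200            5             6         15           1.145            0.005  4.815e-32        True
   C02       OS 200            7             5         14           4.127            0.005  7.491e-46        True
```

Each cohort of 200 patients had 6–7 signature genes planted oncogenic and
protective (|log-hazard| = log 2 per expression SD, 30% censoring). The fit
classifies 11–12 genes as non-neutral per cancer, the permutation p of the
score cutpoint is at its floor (0.005 at 199 permutations), and the
score-high stratum has far worse survival (log-rank p ≈ 1e-32 and 1e-46) —
i.e. the learned score separates the planted risk groups. The per-gene table
is in `fit.directions`:

```
cancer   gene  direction  cutpoint  statistic  z_high     p   naive_p endpoint   n
   C01  ITGA1  oncogenic     22.08      3.254   3.254 0.015  0.001137       OS 200
   C01 ITGA11 protective     3.694      5.493  -5.493 0.005 3.946e-08       OS 200
   ...
```

At this cohort size the fit recovers 83% of the planted gene directions; at
n = 500 recovery exceeds 95% (that experiment is what
`scripts/acceptance.py` reruns). `fit.scores` holds per-sample scores and
strata, `fit.plot_km("C01")` draws the stratified Kaplan–Meier curves, and
`fit.write(outdir)` exports everything as TSV.

The same steps are available from the shell:

```sh
integrinscore simulate --seed 7 --out sim/
integrinscore directions --expr sim/expression.tsv --clinical sim/clinical.tsv --out dirs.tsv
integrinscore score --expr sim/expression.tsv --clinical sim/clinical.tsv \
    --directions dirs.tsv --out scores.tsv
integrinscore run --seed 7 --out full_run/   # end-to-end incl. screens and GSEA
```

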