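# Methods

This note describes the statistical machinery the package implements, the
choices made where the design was genuinely open, what the synthetic cohorts
do and do not emulate, and the known limitations.

## Survival-direction assignment and the signature score

For each cancer type and each signature gene, the gene's expression is tested
against the configured survival endpoint (OS by default, PFS per cancer via
`RunConfig.endpoint_map`) with a **maximally selected rank statistic**: every
distinct expression value is tried as a threshold, subject to a minimum group
proportion `minprop` (default 0.10) on both sides, and the standardized
log-rank statistic |z| of the resulting two-group split is maximised over
thresholds. The log-rank statistic uses the hypergeometric variance summed
over distinct event times; ties in the maximal statistic resolve to the
smallest cutpoint value.

Because the maximum over data-driven splits is optimistic, significance is
assessed by **permutation**: the expression values are permuted against the
(time, event) pairs and the scan re-maximised for each permutation
(`n_perm` default 1000), giving

    p = (1 + #{permutation max >= observed max}) / (1 + n_perm),

which is exact under exchangeability. The naive chi-square p of the selected
split is also reported, but classification uses the permutation p. No further
multiplicity correction is applied on top — the search optimism is absorbed
into the permutation null, and the raw p < 0.05 rule then classifies a gene
as *oncogenic* (high-expression stratum has worse survival, signed z > 0),
*protective* (better survival), or *neutral* otherwise. Genes with
near-constant expression (variance < 1e-12, or too few distinct values to
admit a cutpoint under `minprop`) are classified neutral with a warning so a
single degenerate gene cannot abort a cohort run.

Expression is normalized as **within-cancer z-scores of log2(TPM+1)** —
z-scoring puts oncogenic and protective sums on a common scale; constant
genes map to zeros. The per-sample score is

    score_i = sum_{g oncogenic} z_gi − sum_{g protective} z_gi ,

with neutral genes contributing nothing. A `mode="signed"` variant forces
every gene into the sum with the sign of its survival statistic regardless of
significance, for sensitivity analyses and for scoring cohorts where the
significant-only signature would be empty. Patients are stratified into
score-high/low groups at the score's own optimal cutpoint (same scan), and
the strata compared by log-rank and Kaplan–Meier curves (delegated to
lifelines).

Gene-set *activity* is deliberately simple: the mean z-score over the set's
genes present in the matrix. It is a transparent sample-level summary, not a
reimplementation of kernel-based activity estimators.

## Consensus clustering

The signature transcriptome (samples × z-scored signature genes) is clustered
by the standard Monti resampling scheme: `n_resample` (default 100)
subsamples at `subsample_frac` (default 0.8) are each clustered with k-means
(scikit-learn, seeded); consensus(i, j) is the co-assignment count divided by
the co-sampling count; final labels come from average-linkage hierarchical
clustering on 1 − consensus cut at k. Results for k ∈ {3, 4, 5} can be
compared via the consensus CDF; choosing k remains the caller's decision.
The base clusterer and resample counts are documented test parameters, not
claims of equivalence to any particular published software.

## Correlation screens

All screens share one primitive: tie-aware Spearman correlation with pairwise
deletion of missing values and a t-approximation p-value on n − 2 degrees of
freedom (an exact/Monte-Carlo permutation p is available behind a flag).
Threshold semantics are uniform and follow the published wording exactly:
magnitude cuts are **inclusive** (|ρ| ≥ cut), p-value cuts **strict**
(p < cut), count cuts **strict** ("more than" N).

* **Promoter methylation** — the promoter window is 1000 bp upstream to
  200 bp downstream of the TSS in transcription orientation. Coordinates are
  BED-like 0-based half-open throughout; on the + strand the window is
  [TSS−1000, TSS+200) and the − strand window is its exact mirror, making
  window membership strand-antisymmetric. Among multiple in-window probes the
  one with the highest mean β-value is selected (ties → smaller coordinate);
  genes without an in-window probe are omitted with a logged count. Kept
  pairs: |ρ| ≥ 0.15 and p < 0.05, per cancer.
* **miRNA cascade** — stage 1 drops miRNAs not expressed above 1 in more than
  500 samples pan-cancer (both values configurable; the thresholds assume a
  TCGA-scale cohort, and the demonstration pipeline scales them down to the
  simulated cohort with a logged message); stage 2 keeps pairs with
  |ρ| ≥ 0.3 and p < 0.05 in more than five cancer types; stage 3 intersects
  with a user-supplied validated-pair table (an empty table skips stage 3
  with a loud warning). Every record carries its per-stage flags, and any
  pair passing a later stage necessarily passes all earlier ones.
* **TF screen** — per-cancer correlation over annotated TF–target pairs,
  kept at |ρ| ≥ 0.2 and p < 0.01 (a figure-caption variant of p < 0.05
  exists in the source material; the stricter Methods value is the default
  and both are configurable). TFs are ranked by their count of distinct
  annotated signature-gene targets, top 10 reported with per-cancer percent
  positive/negative among significant pairs.
* **CNV association** — per-gene Kruskal–Wallis across
  amplification/diploid/deletion plus pairwise rank-sum tests and per-state
  medians; any state with fewer than 3 samples skips the gene with a warning.
* **Score-vs-feature association** — per-cancer Spearman of the score against
  immune fractions, immunity-cycle activities, modulators, or drug IC50
  values; drug mode applies |ρ| ≥ 0.1 and p < 0.05 and labels positive-ρ
  compounds *resistant*, negative-ρ *sensitive*. A separate selection rule
  for externally supplied compound enrichment-score tables keeps compounds
  with |score| > 95 in at least ten cancer types.

## Differential ranking and pre-ranked GSEA

The DEG step is intentionally lightweight: genes are ranked by
log2((mean_high + c)/(mean_low + c)) on the TPM scale (pseudocount c = 1),
with two-sided rank-sum p-values and BH adjustment supplying DEG flags at
|FC| ≥ 2 and q < 0.05. This replaces a negative-binomial GLM fit on counts;
downstream enrichment consumes only the ranking, which is what the
replacement preserves. Ties in the metric break by gene identifier for
determinism.

Pre-ranked GSEA uses the classical running sum: hits increment proportional
to |metric|^weight (weight default 1), misses decrement 1/(N − n_set); ES is
the extremum of the running sum. The null is **gene-label permutation**
(random same-size sets, seeded; n_perm default 1000) rather than phenotype
permutation — synthetic strata are small and gene permutation is the
convention for pre-ranked input. NES divides ES by the mean |null ES| of the
same sign; the FDR q follows the standard same-sign pooled null-ratio
procedure, flagged at q < 0.1. Sets smaller than `min_size` (5) in the list,
or covering the whole list, are skipped with warnings.

## Synthetic cohorts and planted ground truth

`simulate_cohort` draws log-normal TPM-like expression with cancer-specific
gene means (Normal(2.0, 0.5) on the log scale, unit within-cancer SD).
Survival follows a **Weibull proportional-hazards** model — shape 1.2 (so KM
curves are non-trivial; an exponential baseline would make the hazard flat),
scale 1800 days — with linear predictor Σ_g β_g z_gi over the planted
signature genes, z being standardized log-expression. Defaults plant a
quarter of the 26 signature genes oncogenic and a quarter protective at
|β| = log 2 per expression SD, a deliberately strong but realistic per-gene
prognostic effect (hazard ratio 2 per SD). Censoring is independent
exponential, calibrated by bisection to a 30% target (tolerance 0.02, error
on failure). PFS is the event time scaled by a per-sample Uniform(0.4, 0.9)
factor with its own calibrated censoring — sufficient for endpoint-switch
tests, not an independent disease-progression model. Optional planted
structure: expression clusters (per-cluster centroid offsets, SD 2.0 on the
log scale when enabled — clearly separated profiles) and per-gene CNV states
(15/70/15% amplified/diploid/deleted, ±1 log-unit shift) applied before
survival generation.

Omics layers and score-correlated features are tied to their anchors through
a **Gaussian copula on ranks**: the anchor is reduced to normal scores of its
ranks, the latent correlation is 2·sin(π·ρ_S/6) so the *Spearman* target
survives the marginal transform (logistic map into (0,1) for β-values,
log-normal for miRNA/TF/feature abundances; |ρ_S| ≥ 0.95 is rejected as the
copula distortion becomes material). Immune fractions are renormalized to
sum to one per sample, which attenuates planted correlations slightly; ICB
response is Bernoulli with logit equal to a stated coefficient times the
standardized score.

What the generator does **not** emulate: count noise and library-size
effects, gene–gene co-expression beyond the planted cluster/CNV structure,
informative censoring, batch effects, or mutation landscapes. Passing tests
therefore demonstrate that the pipeline recovers the structures it assumes
when those structures are present and stays calibrated when they are absent
— not that any particular real-cohort result is reproduced.

## Numerical and calibration notes

* Expression matrices are written with 12-significant-digit floats (TSV
  round-trips to 1e-12); derived result tables use 6 significant digits for
  compact diffs. Reruns from the same configuration are byte-identical.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configurations; the run manifest records seed, config digest and
  package version.
* The null calibration of score-based stratification uses a split-sample
  design: directions (signed mode) are estimated on one null cohort and the
  score is evaluated and stratified on an independent cohort. Estimating
  directions and stratifying on the same data is anti-conservative by
  construction — the gene signs are selected to align with survival noise —
  and that selection effect is a property of the full discovery workflow,
  not of the stratification test this calibration isolates.
* Exact-boundary behaviour of the ρ thresholds (e.g. 0.149 vs 0.15) is
  exercised on the shared filter predicate, since constructing data whose
  sample Spearman lands bit-exactly on a threshold is not robust to
  floating-point rounding; count boundaries are integer-exact and tested
  end-to-end through the cascade.
* Problem sizes in the test suite and acceptance script (cohorts of 200–500
  samples, 20 recovery seeds, 100-replicate null calibrations, 100–200
  permutations per scan) were chosen as the smallest sizes at which the
  planted effects are comfortably identifiable and the calibration estimates
  have usable precision.

## Limitations

* The score ignores integrin heterodimer pairing; it is a linear sum over
  subunit genes.
* The cutpoint permutation p is exact only under exchangeability; covariate-
  dependent censoring would break it.
* Whether all signature genes or only significant ones should contribute to
  the score is genuinely ambiguous in the source formulation; the default is
  significant-only with neutral = 0, and `mode="signed"` exposes the
  all-genes alternative.
* The GSEA FDR uses the pooled same-sign null-ratio procedure; with very few
  sets the pooled null is coarse and q-values are conservative.
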