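# Methods

## Problem setting

Serum cell-free DNA (cfDNA) carries a diluted copy of the tumor methylome.
On methylation arrays this appears as probe-level β-values
(methylated / total intensity, ∈ [0,1]) whose serum profile is a mixture
of tumor-derived and leukocyte-derived fragments.  The package builds two
classifiers on this signal — a diagnostic one (meningioma vs other CNS
entities, *d-MeLB*) and a prognostic one (recurrence risk, *p-MeLB*) — and
surrounds them with the supporting analyses: differential methylation,
consensus clustering of serum methylomes, reference-based immune
deconvolution, methylation–expression integration and recurrence-free
survival.

## Statistical components

**Differential methylation.**  Per probe, a two-sided Wilcoxon rank-sum
test between sample groups: exact null when min(n₁,n₂) ≤ 10 and the pooled
values are tie-free, otherwise the normal approximation with continuity
and tie corrections.  FDR control is Benjamini–Hochberg.  Volcano-style
selection keeps probes with p_FDR ≤ α and diff-mean outside an effect
window; the window may be asymmetric (the serum MNG contrast uses
retain ≥ 0.15 or ≤ −0.175, two separately printed magnitudes exposed as
two configuration values rather than a single symmetric bound).

**d-MeLB construction.**  Per iteration the loop draws (i) a tumor-tissue
significance level p ∈ [1e-4, 0.05] (log-uniform; unadjusted p, which the
randomization range implies), (ii) an SMP similarity bound
δ ∈ [0.1, 0.2] β-units, (iii) a subsample of non-MNG groups, and (iv) a
signature size in [20, 30].  Stages nest by construction:
signature ⊆ SMPs ⊆ tumor-specific DMPs, asserted on every run.  The SMP
bound is interpreted in absolute β units: a 0.001–0.002 tolerance would
retain essentially nothing while the stage is expected to keep thousands
of probes, so the percent sign on the printed range is treated as a typo.
Scores are the fraction of trees voting positive in a bagged
decision-tree ensemble (random forest, 1000 trees, 10-fold stratified CV
reported); a score at the cutoff classifies positive.  Model selection
maximizes model-selection-set AUC (ties: higher MCC at the Youden cutoff,
then lower iteration index); the deployed cutoff maximizes Youden's
J = Se + Sp − 1 over midpoints of consecutive sorted unique scores.

**p-MeLB construction.**  The derivation intersects probes differential
between confirmed-recurrence (CR) and confirmed-non-recurrence (CNR)
training tissue with probes differential between adverse- and
favorable-outcome serum clusters (adverse = clusters with above-average CR
rate), with all four thresholds (two p_FDR levels, two effect minima)
drawn per iteration; an empty intersection signals a degenerate draw and
the loop resamples.  CNR requires ≥ 60 months of event-free follow-up (the
five-year rule), enforced by the sample-sheet validator.  The iteration
with the smallest out-of-bag (OOB) error wins; its cutoff minimizes OOB
misclassification over a 0.30–0.70 grid with 0.01 steps, ties resolving
toward 0.50.  When every draw is degenerate — the expected behavior when
tissue outcomes carry no methylation signal — the pipeline reports no
stratification instead of fabricating a classifier.

**Consensus clustering.**  k-means (k-means++, 10 restarts) on random 80%
sample subsamples of the 1000 most-variable probes; consensus(i,j) =
co-clustering count / co-sampling count; the final partition for each k is
an average-linkage hierarchical cut of 1 − consensus.  The number of
clusters is chosen by stability: the PAC statistic (fraction of consensus
entries in (0.1, 0.9), a summary of the consensus CDF) is ≈ 0 for every k
at which resampled partitions agree and jumps once k exceeds the real
group count; the selected k is the largest k with PAC ≤ 0.05, or the
smallest candidate k when no k is supported (no structure).  A
CH-maximizing rule constrained by the CDF-area curve was evaluated first
and proved unstable — the Calinski–Harabasz index computed on the raw
feature matrix is dominated by background probes and often peaks at the
coarse two-group split — so CH and CDF-area curves are reported as
diagnostics rather than used as the selector.

**Deconvolution.**  Nonnegative least squares of each sample's β-vector on
the atlas columns, fractions < 1e-4 truncated, then normalized to sum 1.
This is a deterministic constrained-least-squares stage; the quantity that
matters downstream is mixture recovery, which is what the tests measure.
NLR = neutrophil / (B + CD4T + CD8T + NK); an empty lymphocyte denominator
with nonzero neutrophils is flagged infinite.

**Metrics.**  MCC with the zero-marginal → 0 convention; clinical utility
indices CUI+ = Se×PPV and CUI− = Sp×NPV graded excellent/good/
satisfactory/poor at ≥0.81/≥0.64/≥0.49/<0.49 (closed on the left);
unweighted Cohen's κ; AUC as pairwise concordance; Fisher's exact
two-sided p by the probability-mass rule with Haldane-corrected OR and
logit-normal CI (flagged approximate); Welch t with Satterthwaite df;
Pearson/Spearman correlations.  CUI values are reported as fractions
throughout.

**Survival.**  Product-limit estimator with Greenwood variance; events
precede censorings at tied times; time unit is months.  Fixed-horizon
survival (default 60 months) is a right-continuous step lookup, flagged
when the horizon exceeds follow-up.  Log-rank is the standard two-group
test with hypergeometric variance; a cohort with no events returns p = 1.

## Synthetic cohort design

The generator produces the statistical structure the analysis assumes,
not a forgery of any real dataset.  Defaults (one reference scenario used
by all tests):

| parameter | default | rationale |
|---|---|---|
| probes | 4000 | smallest panel on which all stages have headroom (1000 top-variance probes, 300-probe immune block, planted sets) |
| serum cohort | 50 MNG / 50 non-MNG (glioma 20, glioblastoma 10, pituitary 10, control 10) | balanced two-group default at the scale where rank tests are comfortably powered |
| tissue cohort | 50 paired MNG + 50 tissue-only MNG + 20 nontumor brain | paired samples feed the SMP filter; the tissue-only series carries the prognostic contrast |
| planted probes | 120 diagnostic, 80 prognostic, 4×50 cluster, 60 glioblastoma, 300 immune | disjoint blocks so recovery is unambiguous |
| effect sizes Δβ | 0.3 (diagnostic, prognostic, cluster) | mid-range array effect; planted baselines are drawn mid-interval so shifts never clip |
| tumor fraction in serum | 0.8 | paired serum–tissue correlation ~0.95 and serum effects at ~0.8×Δβ, consistent with a pipeline whose SMP stage expects serum ≈ tissue |
| β noise | Beta(μc, (1−μ)c), c = 60 | respects [0,1], heteroscedastic like arrays (sd ≈ 0.06 at μ = 0.5); c = ∞ gives the noise-free limit |
| hazards | low-risk 0.001/month, hazard ratio 30, follow-up U(6, 120) months | ≈76% of high-risk and ≈6% of low-risk patients recur within follow-up, echoing a strong prognostic separation (5-year RFS ≈ 0.1 vs ≈ 0.9) |

Latent risk (high/low) is the design cell; the CR/CNR/unknown outcome is
*derived* from a simulated exponential event time against uniform
follow-up (event → CR; event-free ≥60 months → CNR; else unknown).  This
makes outcome labels honestly noisy with respect to the planted
methylation risk signal, and makes the hazard-ratio-1 null coherent: with
equal hazards, predicted risk arms show no survival difference, which the
pipeline null-calibration test checks.

Serum values are tf·tumor + (1−tf)·blood, where blood carries
Dirichlet immune fractions over a reference atlas on the immune probe
block (high-risk patients get a doubled neutrophil concentration
parameter, producing the outcome-linked neutrophil/NLR shift).  Serum
cluster identity is risk-aligned (high-risk samples fall in the adverse
half of the clusters) with cluster-specific probe shifts applied on the
serum scale.

What the generator does **not** emulate: probe-probe correlation
structure (CpG co-methylation blocks), batch effects, varying per-sample
tumor fraction, copy-number interference with β, age/sex covariates, and
read-level noise.  Passing tests therefore demonstrate that the
implementation recovers the structures it targets under the stated model,
not clinical performance on patient cohorts.

## Numerical choices

- Top-k probe selection breaks ties by larger |diff-mean|, then lexical
  probe id, so signatures are deterministic.
- KNN imputation (k = 5 default) uses nan-Euclidean distances over
  pairwise-complete sample columns; neighbors must share ≥3 observed
  columns (capped at the target's own observed count); imputed values are
  clipped to [0,1]; observed entries are never altered.
- Coordinates are 0-based internally; annotation files may declare
  1-based input (`#coords=1-based`) and are shifted on read; the promoter
  window is ±200 bp around a TSS.
- The tissue linear discriminant uses a pooled within-class covariance
  with ridge λ = 1e-3·trace/p, which keeps the solve well-posed when
  probes outnumber samples.
- Iteration seeds are drawn from one master generator, so a bundle's
  provenance (iteration index + seed + drawn thresholds) replays exactly.
- Test-scale runs use the pipeline's fast mode (50 iterations, 100
  consensus resamples, 300 trees, 5 CV folds); the construction loops
  default to 1000 iterations/resamples/trees.

## Known limitations

- The prognostic derivation is one concrete, documented realization of a
  "sequential supervised analyses" idea; other intersection orders or
  threshold families are plausible.
- The CR/CNR accuracy of p-MeLB is bounded by the latent-risk/outcome
  coupling of the survival model; at mild hazard ratios outcome labels
  decouple from the methylation signal and held-out accuracy necessarily
  falls, which is a property of the design, not a bug.
- Deconvolution of serum underestimates immune shifts by the factor
  (1 − tumor fraction), since only the blood component carries them.
- Fisher CIs are logit-normal approximations; no exact CI is attempted.
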