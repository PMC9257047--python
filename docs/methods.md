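# Methods

## The model

`irlncpair` implements a rank-based prognostic signature for bulk tumor
transcriptomes. The unit of modelling is not a gene's expression level but
the *within-sample order* of a pair of immune-related long non-coding RNAs
(lncRNAs): the binary feature

    value(A, B; s) = 1  iff  expr_A(s) > expr_B(s)   (strictly; ties -> 0)

for pair {A, B} in sample s. Because it compares two measurements taken on
the same sample, the feature is invariant to per-sample scaling and
monotone normalization, which is what makes a pair signature portable
across platforms. The pipeline derives a single such pair whose order
stratifies patients into high-risk (riskScore 1) and low-risk (riskScore
0) groups under a proportional-hazards model for overall survival.

Stages, with their gates:

1. **Immune correlation screen.** A lncRNA is immune-related when it
   correlates with at least one immune gene at Pearson r > 0.5 and
   p < 0.001 (strict inequalities; all samples by default, tumor-only via
   a switch).
2. **Differential expression.** Two-group empirical-Bayes moderated t
   between tumor and normal; keep |log2 fold change| >= 1.5 (inclusive)
   and p < 0.05. The up/down direction label feeds the later same-trend
   rule.
3. **Survival screen.** Per-lncRNA univariate Cox on continuous log2
   expression, Wald p < 0.01; then one joint multivariate Cox on the
   survivors, Wald p < 0.05. Survivor sets are nested by construction.
4. **Pair construction.** All C(k,2) pairs of survivors, canonical
   lexicographic orientation; pairs whose one-frequency falls outside the
   closed band [0.2, 0.8] cannot grade the cohort and are dropped.
5. **Pair selection.** Univariate Cox on each binary pair feature
   (p < 0.05); LASSO-Cox over the survivors (CV-selected lambda; if the
   active set is empty, the nearest lambda with a non-empty set is used
   and flagged); joint multivariate Cox on the active set; restriction to
   pairs whose members share the DE direction ("same expression trend");
   at least one member must show a significant median-split Kaplan-Meier
   log-rank (p < 0.05); ties broken by smallest multivariate Wald p. A
   cohort with no qualifying pair yields an explicit no-signature result,
   never a fallback.
6. **Evaluation and characterization.** Kaplan-Meier curves and log-rank
   between risk groups; univariate and multivariate Cox with stage/T/N/M
   (ordinal integer codes); infiltration and checkpoint contrasts
   (Mann-Whitney + Spearman, BH-adjusted alongside raw p); single-gene
   analyses; GSEA; co-expression export.

The orientation convention follows the clinical reading: riskScore 1 when
the hazardous member's expression is >= the protective member's (a tie is
treated as high risk).

## Statistical primitives

All core statistics are implemented from their definitions; SciPy supplies
only distribution functions and digamma/trigamma.

* **Pearson/Spearman.** Product-moment formula; p from
  t = r sqrt((n-2)/(1-r^2)) on n-2 df. Spearman is Pearson on mid-ranks,
  so ties are handled by averaging. Constant vectors raise an explicit
  undefined-correlation error that callers treat as "not correlated".
* **Mann-Whitney rank-sum.** Mid-ranks; exact two-sided p by full
  enumeration of rank assignments when n1+n2 <= 12 and no ties are
  present, otherwise the normal approximation with tie correction and a
  0.5 continuity correction. (The two-independent-group comparison is the
  rank-sum test; the signed-rank variant applies to paired data, which
  risk groups are not.)
* **Moderated t.** Per gene, pooled two-group variance s_g^2 on d_g df;
  the inverse-chi-square prior (d0, s0^2) is fitted by method of moments
  on log s_g^2 (digamma/trigamma moment equations, trigamma inverted by
  Newton); posterior variance (d0 s0^2 + d_g s_g^2)/(d0 + d_g); t on
  d0 + d_g df. A non-positive moment estimate falls back to d0 = infinity
  (all variances shrink to s0^2). `prior_df=0` reproduces the ordinary
  pooled t exactly, which the tests exploit.
* **BH adjustment.** Standard step-up. Note that BH is *not* idempotent
  in general (p = [0, 0.5, 1] maps to [0, 0.75, 1] and then [0, 1, 1]);
  the tests assert bounds, dominance over raw p and order preservation
  instead.
* **Kaplan-Meier / log-rank.** Product-limit over distinct event times;
  at tied times events precede censorings, so a sample censored at an
  event time is still at risk. Log-rank uses the hypergeometric variance
  summed over event times, chi-square on 1 df.
* **Cox.** Newton-Raphson on the Efron-approximated partial likelihood
  (Breslow behind a flag), step-halving so the log-likelihood never
  decreases, convergence at max |score| < 1e-8 or relative likelihood
  change < 1e-9 within 50 iterations. |beta| > 20 flags monotone
  likelihood (separation) and the fit is reported non-converged rather
  than trusted. SEs from the inverse observed information; 95% CI as
  exp(beta +/- 1.96 se).
* **LASSO-Cox.** Cyclic coordinate descent on the penalized objective
  -(1/n) l(beta) + lambda ||beta||_1 with internally standardized
  covariates, outer quadratic approximation with diagonal weights, warm
  starts along a 50-point log-spaced grid descending two decades from
  lambda_max (the smallest all-zero lambda, held exact). Cross-validation
  uses the Verweij-van Houwelingen partial-likelihood deviance with folds
  a pure function of (seed, n); selection is minimum-deviance
  ("lambda.min") with "lambda.1se" as an option. When all survival times
  are distinct (the generic case for continuous times) the per-observation
  derivatives use a vectorized path where Efron and Breslow coincide; the
  tie-handling loop path and the fast path are both checked against
  numerical gradients.
* **GSEA.** Weighted Kolmogorov-Smirnov running sum with weight p = 1:
  hits step up by |metric|^p normalized over hits, misses step down by
  1/(N - N_hit); ES is the signed extremum. Significance by phenotype
  permutation (default 1000, seeded) of the top-50%/bottom-50% split, the
  signal-to-noise metric (mean difference over summed SDs, denominator
  floored at 1e-8) recomputed per permutation; NES = ES / mean |null ES|
  of matching sign; p = (1 + #{null at least as extreme, same sign}) /
  (1 + n_perm), so p is never 0.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the reference study scale: 300 tumors, 50 normals, 60 lncRNAs, 120 coding
genes, 30 immune genes, planted pair log-hazard log 2.5, 30% censoring.
Expression is Gaussian on the log2 scale (baseline means ~N(6,1), residual
sd 0.5): the pipeline consumes processed expression, so count-level noise,
batch effects and molecular subtypes are deliberately out of scope.

Structure is planted through two latent factors:

* an immune factor z shared by most immune genes (loading 0.9) and by the
  immune-coupled lncRNAs, which makes the r > 0.5 screen recover them;
* a pair factor u carried with loadings +c and -c (c = 0.47) by the two
  pair members and with +/-0.9 by four immune genes. The within-sample
  order I[A > B] is then driven by u, each member remains strongly
  coupled to its own order indicator, and each member stays correlated
  above 0.5 with an immune gene. The four u-coupled immune genes share
  the members' tumor up-shift so the correlation screen, which runs
  across all samples, sees the shift as covariance rather than noise.

Twelve lncRNAs get a +/-2.0 log2-unit tumor shift (both pair members up,
matching the same-trend rule); the rest of the immune-coupled lncRNAs are
survival-null by construction because z is independent of u.

Survival times are exponential with hazard
(1/baseline_scale) exp(beta I[A>B] + stage terms). Stage, T, N, M are
categorical (4/4/3/2 levels) with log-linear hazard increments and a
strong metastasis multiplier (log HR 1.05), so M=1 reproduces the
qualitative "independent predictor" behaviour. The staging *distributions*
of high-risk patients are shifted toward later stages
(`stage_risk_coupling`, default 1): a prognostic signature in a real
cohort co-varies with clinicopathology, and without this coupling the
two-stage screen cannot pass both members at the reference effect size —
the univariate and multivariate screen z-statistics trade off against each
other (their squares sum to a constant set by beta and the event count)
and both gates cannot clear jointly on the pair indicator alone.
Censoring is independent exponential with its rate solved by bisection to
hit the requested censoring fraction; non-informative by construction.

Infiltration fractions are Dirichlet draws (concentration 200) whose mean
vector shifts by 0.05 between risk groups for the designated cell types
(CD8/CD4 T cells, neutrophils, M1 macrophages, plasmacytoid dendritic
cells down in high risk; fibroblasts and M2 macrophages up). Because the
fractions live on the simplex, mass removed from down-shifted types
necessarily appears in the unshifted remainder, so small positive shifts
of nominally unshifted cell types are expected and real. Checkpoint genes
(CD27, PDCD1, IDO1 down; CD276 up) and one 20-gene enriched set shift
with the realized risk label inside the expression matrix.

All randomness flows from one master seed through named
`SeedSequence.spawn` sub-streams (expression / survival / infiltration),
so stages regenerate independently and identical configuration + seed is
bit-identical.

What passing tests on this generator do **not** show: robustness to
count-level overdispersion, batch structure, subtype heterogeneity,
informative censoring, or missing clinical covariates. The generator is a
correctness instrument, not a realism benchmark.

## Numerical and design choices

* Ties in the pair feature binarize to 0 (strictly-greater rule);
  measure-zero for continuous data but fixed and tested for determinism.
* The 20-80% frequency band is closed at both ends.
* "Same expression trend" means identical DE direction labels.
* Median splits send exact-median samples to the low group; with an odd
  cohort the groups differ by at most one sample.
* Multivariate retention threshold after the univariate survival screen
  is p < 0.05; correlation screening uses all samples — both choices are
  configurable since the upstream description leaves them open, as are
  the tie approximation (Efron default), fold count (10) and lambda rule
  (minimum deviance).
* No imputation anywhere: the expression reader rejects missing values;
  clinical NAs are carried explicitly and handled by listwise deletion,
  with matched-sample counts recorded in the run summary.
* Reported p-values are clamped to the smallest positive double rather
  than printed as 0.

## Problem sizes in the test suite

The acceptance checks run at the reference scale (50 seeds of the
300-tumor cohort for recovery and 50 for the null, 2000 null simulations
for log-rank calibration at 100 samples per arm, 20 seeds for LASSO
recovery at n = 300 with 10 noise covariates, all 1140 placements of a
3-gene set for the GSEA oracle). These sizes give binomial standard
errors comfortably inside the asserted bands while keeping the full suite
within a few minutes on one core.

## Known limitations

* The final signature is a single pair; multi-pair composite scores are
  out of scope.
* Deconvolution (CIBERSORT and relatives) is not implemented;
  infiltration fractions are consumed as an input table.
* No time-varying covariates, stratified Cox, elastic-net mixing, or
  robust variance.
* Connectivity-map queries are not performed; only the co-expression
  gene list is exported.
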