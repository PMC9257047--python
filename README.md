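# irlncpair

Rank-based prognostic signatures from immune-related lncRNA pairs.

## The problem

Prognostic gene signatures built on absolute expression levels transfer
poorly between cohorts: platform, library size and normalization all move
the numbers. A *pair* signature sidesteps this by scoring only the
within-sample order of two genes — the binary feature

```
value(A, B; sample) = 1  iff  expr_A > expr_B   (else 0)
```

is invariant to any per-sample monotone transformation. `irlncpair`
implements, as a tested and reusable library, the full analysis that
derives such a signature for a breast-cancer-style cohort from bulk
transcriptomes and immune gene sets:

1. immune-related lncRNAs by correlation with immune genes
   (r > 0.5, p < 0.001);
2. differentially expressed candidates by empirical-Bayes moderated t
   (|log2FC| >= 1.5, p < 0.05);
3. prognostic candidates by univariate (p < 0.01) then multivariate
   (p < 0.05) Cox regression on overall survival;
4. the 0-or-1 pair matrix over all candidate pairs, filtered to pairs
   whose one-frequency lies in the closed 20–80% band;
5. a single final pair by univariate pair Cox, LASSO-Cox with
   cross-validation, multivariate Cox, a same-expression-trend rule and a
   median-split Kaplan–Meier rule;
6. risk stratification (riskScore ∈ {0,1}) and downstream
   characterization: KM/log-rank, clinicopathological Cox models, immune
   infiltration and checkpoint contrasts, GSEA, and a co-expression gene
   list for connectivity-map queries.

The survival machinery (Kaplan–Meier, log-rank, Newton–Raphson Cox with
Efron ties, coordinate-descent LASSO-Cox), the moderated-t differential
expression, the rank/correlation tests and the weighted-KS enrichment
score are all implemented from first principles and cross-checked in the
test suite against lifelines, glmnet, limma, scipy and statsmodels as
independent oracles.

Because the original tumor cohort cannot be redistributed, the package
ships a synthetic-cohort generator (`irlncpair.simulate`) that plants the
exact structure the analysis assumes — immune-correlated lncRNAs, a
prognostic pair whose within-sample order drives a proportional hazard,
censored survival with stage/T/N/M covariates, risk-shifted infiltration
fractions and checkpoint genes — together with a ground-truth record, so
every stage is testable end to end.

## Worked example

```python
from irlncpair import CohortConfig, PipelineConfig, generate_cohort, run_pipeline

expr, truth, clinical = generate_cohort(CohortConfig(seed=1))
lnc_ids = [g for g in expr.values.index if g.startswith("LNC")]
result = run_pipeline(expr, clinical, lnc_ids, truth.immune_gene_ids,
                      config=PipelineConfig(seed=1))
sig = result.signature
print(sig.pair, sig.rule)
print(result.summary["counts"], result.summary["evaluation"])
```

prints (seed 1):

```
('LNC0001', 'LNC0002') riskScore = 1 (high risk) iff expr[LNC0001] >= expr[LNC0002] ...
{'irlncrna': 15, 'de_irlncrna': 12, 'unicox': 2, 'multicox': 2}
{'logrank_chi2': 78.49..., 'logrank_p': 8.04e-19,
 'riskScore_uni_HR': 3.665, 'riskScore_uni_p': 5.4e-17,
 'riskScore_multi_HR': 2.915, 'riskScore_multi_p': 4.9e-11}
```

Reading: of 60 lncRNAs, 15 pass the immune screen, 12 are differentially
expressed, and exactly the two planted pair members survive the Cox
screens; the selected pair is the planted one with the correct
orientation (samples where LNC0001 dominates are high-risk). The risk
groups separate strongly on survival (log-rank p ≈ 8e-19) and the
riskScore remains an independent predictor (HR 2.9) after adjusting for
stage, T, N and M. The `examples/` directory walks each capability with
a short narrative script (`python examples/03_pair_signature.py` and so
on), and the `irlncpair` CLI offers `simulate` and `run-all` for
file-based runs.

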