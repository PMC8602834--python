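# reactsig

Tumor-reactive T-cell signature derivation, scoring and survival evaluation.

Only a subset of the T cells infiltrating a tumor actually recognize tumor
antigens; the rest are bystanders, so total CD8+ infiltration is a noisy
proxy for anti-tumor immunity. `reactsig` implements a transcriptomic
workflow that (i) derives a tumor-reactive signature (TRS) from a
cluster-labeled single-cell expression matrix in which one state — the
exhausted, clonally expanded compartment — marks tumor-reactive cells,
(ii) scores bulk tumor samples and single cells for that signature,
(iii) prunes the signature against survival data, and (iv) quantifies the
score's prognostic and immunotherapy-response value. It is aimed at
computational immunologists who want each statistical step as an
inspectable, tested primitive rather than a chain of R packages.

Everything runs on seeded synthetic data generated in-package, so the whole
pipeline is testable end to end without any external download.

## The statistics at the core

**Signature derivation.** For target cluster *C* and each gene *g*, a
one-sided Wilcoxon rank-sum test (BH FDR < 0.05) flags genes up-regulated
in *C*; each candidate's one-vs-rest discrimination is the ROC AUC
`AUC_g = P(x_C > x_rest) + ½ P(x_C = x_rest)`, and the signature is the
top *k* = 20 candidates by AUC.

**Per-sample scoring** (five statistics): the GSVA kernel-CDF KS walk
(`ẑ_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i)`, `h_i = s_i/4`, then a
symmetrized-rank weighted Kolmogorov–Smirnov walk), the ssGSEA
rank-weighted KS walk, the combined z-score `Σ_{g∈S} z_gj / √|S|`, the
PLAGE first right singular vector of the z-scored signature submatrix, and
the plain mean. Per-cell scoring uses the AUCell ranking-recovery curve:
the normalized area under the count of signature genes found within the
top-ranked fraction of each cell's genes.

**Refinement.** Backward elimination: score the cohort on the current gene
set, fit a univariate Cox model on the score, try every single-gene
deletion (re-scoring each time), accept the deletion with the lowest AIC if
it is strictly below the current AIC, repeat until no deletion helps.

**TCR clonality.** A clonotype is an exact paired alpha-beta chain; clone
size 1/2/≥3 maps to unique/repeated/clonal, and per-sample diversity is
Shannon entropy rarefied by repeated downsampling to a common depth.

**Survival evaluation.** Kaplan–Meier with median-split stratification and
the log-rank test; Cox proportional hazards via Newton–Raphson on the
Efron partial likelihood; Harrell's C-index; cumulative/dynamic
time-dependent ROC AUC with KM censoring weighting; and restricted mean
survival time (area under the KM curve to a horizon τ) compared across
arms as a ratio.

## Worked example

```python
import reactsig as rs

# simulate a landscape whose state S1 over-expresses 40 planted genes
expr, ann = rs.gen_sc_dataset(rs.ScDesign(seed=7))
markers = rs.wilcoxon_markers(expr, ann.states(), "S1")
aucs = rs.gene_auc(expr, ann.states(), "S1")
sig = rs.derive_signature(markers, aucs, k=20)
print(len(sig), len(set(ann.truth["planted_genes"]) & set(sig.genes)))
# 20 20    <- a 20-gene signature, all 20 from the planted program

# score a survival cohort whose hazard falls with the latent score
bulk, surv, _ = rs.gen_bulk_cohort(rs.CohortDesign(n_samples=300, seed=9),
                                   rs.GeneSignature(genes=[f"SIG{i}" for i in range(10)]))
sv = rs.score_samples(bulk, rs.GeneSignature(genes=[f"SIG{i}" for i in range(10)]),
                      rs.ScoringConfig(method="kcdf_ks"))
grp = rs.stratify_median(sv.scores)
print(rs.logrank_test(surv["time"], surv["event"], grp.reindex(surv.index))["p"])
# 9.3e-09  <- high-score samples survive longer
```

The scripts in `examples/` walk through each capability (simulation,
derivation, the five scorers, clonality, survival metrics, refinement and
response prediction) and print the numbers with one-line interpretations.
A thin CLI mirrors the library:

```bash
reactsig run --config pipeline.yaml --out-dir out --seed 1
reactsig simulate sc --out-dir out --seed 7
reactsig derive --expr out/sc_expression.tsv --labels out/sc_annotation.tsv \
    --target S1 --out out/sig.gmt
```

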