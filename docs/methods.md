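# Methods

This note records the models, conventions and numerical choices behind
`reactsig`, and what the synthetic study conditions do and do not show.

## Synthetic data model

The generators produce data with exactly the statistical structure the
analysis assumes, plus ground truth for recovery testing.

**Single-cell landscape** (`gen_sc_dataset`). Cells are assigned uniformly
to `n_states` discrete states and `n_patients` patients. Expression is
Gaussian on the log2 scale, `N(base_mean, noise_sd²)` (defaults 2 and 1),
clipped at zero; a random set of `n_signature_genes` genes (default 40 of
500) gains an additive `marker_shift` (default 2 log2 units) in the
reactive state only. Dropout is independent Bernoulli zero-inflation
(default rate 0.1) — adequate for exercising detection-rate filters, not a
claim about the biology of dropout. States other than the reactive one are
distinguished only by their labels; the generator does not emulate batch
effects, nested patient structure, compositional shifts, or
cell-cycle/interferon confounding. Passing tests on this landscape
therefore show that the derivation machinery recovers a planted additive
program at realistic size and noise — not that it resolves correlated
confounders in real atlases (the choice of which cluster to derive from
remains the analyst's).

**Clonotypes** (`gen_tcr_table`). Within each patient, cells are visited in
random order; a cell either founds a fresh clonotype (weight = remaining
fresh pool, default 40 per patient) or joins an existing non-full clone
(weight = `join_weight` × clone size, default 0.1, capped at
`max_clone_size` = 60). For reactive-state cells the joining odds are
multiplied by `clonal_enrichment` (default 5). The small `join_weight`
makes expansion be driven by the enrichment multiplier and by pool
exhaustion; with a pool at least as large as the cell count and no
enrichment, nearly all clones are singletons. Identifiers are opaque
`TRA:k|TRB:k` strings — only pair uniqueness matters; no sequence realism
is attempted.

**Bulk cohorts** (`gen_bulk_cohort`, `gen_response_cohort`). A latent
reactivity score u ~ N(0,1) per sample adds `signature_loading` (default 1)
log2 units per unit u to every signature gene; `n_genes` (default 1000)
total genes provide the background universe the rank-based scorers need.
Survival is exponential with hazard `baseline_hazard · exp(latent_effect ·
u)` (defaults 0.1 and −0.7: higher reactivity, lower hazard), censored by
an independent exponential (rate 0.05). The exponential model was chosen
over Weibull because its closed-form hazard makes parameter-recovery
oracles exact. Responder labels are Bernoulli with
`P = logistic(response_logit_slope · u)` (default slope 2).

## Derivation conventions

The marker test is one-sided (greater in target) because the signature is
defined from over-expressed genes; a two-sided mode exists for parity
checks. Exact enumeration is used when the combined group size is ≤ 20 and
there are no ties; otherwise the normal approximation with midranks, tie
correction and continuity correction. BH adjustment runs over all tested
genes. The top-k selection breaks AUC ties lexicographically by gene id; if
fewer than k candidates pass, all are returned with a provenance warning.
Default k = 20.

## Scoring conventions

* `kcdf_ks`: Gaussian kernel bandwidth `s_i/4` per gene; Poisson kernel
  rate `x + 0.5` for raw counts. Zero-variance genes are given a constant
  0.5 kernel row rather than dropped so gene universes stay aligned across
  methods. Walk weight exponent tau = 1 and enrichment mode `max_diff`
  (largest positive deviation minus largest absolute negative deviation)
  are the defaults; `max_abs` is available.
* `rank_weighted_ks`: in-set increments proportional to
  (ascending midrank)^alpha with alpha = 0.25; the score is the sum of the
  running differences, divided by the cohort's score range when
  normalization is on (default).
* `first_singular_vector`: the singular vector's sign is arbitrary, so by
  default it is oriented to correlate non-negatively with the mean
  signature z-score; the raw unoriented vector is available
  (`orient_singular_vector=False`) for strict parity with conventions that
  leave the sign free — without orientation, higher scores need not mean
  higher activity.
* Ranking recovery: threshold T = ceil(top_fraction × n_genes), default
  fraction 0.05; score = Σ_{t≤T} hits(t) / Σ_{t≤T} min(t, k) ∈ [0, 1].
  Per-cell ties are broken by a seeded shuffle by default; a deterministic
  first-occurrence mode supports exact tests. A signature larger than T
  warns (scores cannot reach 1) instead of failing.

These defaults are validated by literal-transcription oracles (a
hand-written loop re-implementing each definition) at tolerance ≤ 1e−10,
not against any external implementation.

## Clonality

Clonal classes: size 1 unique, 2 repeated, ≥ `clonal_min_size` (default 3)
clonal. Rarefied diversity is Monte-Carlo: `n_replicates` (default 1000)
seeded subsamples of `depth` cells without replacement, natural-log Shannon
entropy of clonotype frequencies, reported as mean ± SD; the estimator is
validated against exhaustive subsample enumeration on small repertoires.
Depth defaults to the minimum repertoire size across samples; samples below
depth are reported missing, never extrapolated. Note the reported quantity
is entropy (diversity); conventional "clonality" is 1 − normalized entropy,
so the two move in opposite directions.

## Survival machinery

Cox fits maximize the Efron-ties partial likelihood (Breslow behind a
flag) by Newton–Raphson with step halving; covariates are centered for
numerical stability (the estimate is unaffected). Convergence requires the
maximum score component below 1e−9 within 50 iterations; a Newton step
below 1e−12 in magnitude also terminates (the likelihood is flat at float
resolution), and the step-halving floor tolerates log-likelihood changes
within 1e−10 relative so roundoff near the optimum cannot stall the line
search. Coefficients beyond |β| = 22 are flagged as monotone likelihood
(perfect separation) and capped. Standard errors come from the observed
information; AIC = −2 logL + 2p exactly.

C-index: pairs are usable when the subject with the shorter time has an
event; tied times with both events are unusable; tied times with exactly
one event count the event subject as shorter; risk ties score ½.
C-index differences between two risk scores are tested by paired bootstrap
(default 1000 resamples, percentile CI) rather than an analytic U-statistic
variance — simpler, seeded, and adequate for the significance stars it
feeds.

Time-dependent AUC is the cumulative-case/dynamic-control estimator with
Kaplan–Meier censoring weighting: per risk cutpoint, sensitivity and
specificity are derived from the KM survival of the above-cut subset via
Bayes inversion, and the AUC is the trapezoid integral over the resulting
ROC. The KM variant was chosen as the parameter-free option (the
alternative nearest-neighbor smoother needs a span parameter no analysis
here fixes). Without censoring before the horizon it reduces exactly to
the plain binary AUC. The evaluation horizon is configuration; the default
used in reports is the median observed time.

RMST integrates each arm's KM step function on [0, τ] exactly; τ defaults
to the minimum over arms of the last observed time, and a τ beyond an
arm's follow-up is an error unless that arm's curve has already reached
zero. The CI uses the Greenwood-based variance of RMST and the delta
method on the log scale; the ratio is arm2/arm1 on sorted labels with the
order stated in the output.

Median-split stratification sends ties at the median to the low group
(documented because group sizes depend on it); all-constant scores are an
error. Score-type signatures are negated into risk scores so that higher
risk uniformly means worse survival.

## Refinement

Strict-inequality acceptance: equal AIC stops the loop (an "didn't
decrease" rule), argmin ties break lexicographically. The in-loop scorer
defaults to the kernel-CDF statistic but any per-sample method is
pluggable; the kernel transform depends only on the matrix and is computed
once per refinement run. Because every fit is univariate, an AIC decrease
is equivalent to a partial log-likelihood increase, asserted at every
accepted step. The final set is never empty; no minimum-size floor beyond
1 is imposed.

## Pipeline and provenance

A single global seed fans out to per-stage seeds via
`SeedSequence([seed, stage_index])`, so any stage can be re-run in
isolation from the seed recorded in the report. Artifact-level provenance
(version, config hash, per-stage seeds) lives in the run's `report.json`
rather than in comment headers inside each TSV, keeping the TSVs plainly
machine-readable.

## Problem sizes and limitations

Default study conditions: 500 genes × 600 cells, 4 states, 40 planted
genes at shift 2; cohorts of 200–500 samples with 1000-gene universes;
20-seed replications for recovery checks and 100-seed replications for
type-I calibration. These sizes make every oracle check exact or tightly
Monte-Carlo-bounded while keeping the full suite fast. Known limitations:
the generators produce independent Gaussian genes (no correlation
structure, no compositional effects), the clonotype process is a schematic
preferential-attachment model, and the DE rule's Welch t-test is applied
to log-scale values as given (no variance moderation). The Wilcoxon exact
path is limited to untied samples of combined size ≤ 20; beyond that the
continuity-corrected normal approximation is used.
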