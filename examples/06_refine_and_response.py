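"""Refine a signature by stepwise AIC and predict immunotherapy response.

A pure-noise gene appended to an informative signature should be the first
deletion accepted by the backward-elimination loop. The refined signature
is then scored on a response cohort where responder probability rises with
the latent reactivity score.
"""

import pandas as pd
import numpy as np

import reactsig as rs

informative = [f"SIG{i}" for i in range(5)]
design = rs.CohortDesign(n_samples=400, n_genes=80, seed=21)
expr, surv, _ = rs.gen_bulk_cohort(design, rs.GeneSignature(genes=informative))
noise = pd.DataFrame(
    design.base_mean + np.random.default_rng(99).normal(0, 1, size=(1, 400)),
    index=["NOISE0"], columns=expr.observations,
)
full = rs.ExpressionMatrix(pd.concat([expr.values, noise]), "log2")
signature = rs.GeneSignature(genes=informative + ["NOISE0"])

refined, trace = rs.stepwise_aic_refine(
    full, signature, surv, rs.ScoringConfig(method="mean")
)
print(f"refinement: {len(signature)} -> {len(refined)} genes")
for step in trace.steps:
    print(f"  removed {step['gene_removed']:7s} "
          f"AIC {step['aic_before']:.2f} -> {step['aic_after']:.2f}")

rexpr, labels, _ = rs.gen_response_cohort(
    rs.CohortDesign(n_samples=300, seed=13), refined
)
sv = rs.score_samples(rexpr, refined, rs.ScoringConfig(method="combined_z"))
res = rs.response_auc(pd.DataFrame({"responder": labels, "score": sv.scores}))
print(f"response cohort: {res['n_responders']} responders / "
      f"{res['n_nonresponders']} non-responders")
print(f"response AUC = {res['auc']:.3f} (rank-sum p = {res['ranksum_p']:.2e})")
# The noise gene goes first with a strictly decreasing AIC trace, and the
# refined score separates responders from non-responders well above chance.
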