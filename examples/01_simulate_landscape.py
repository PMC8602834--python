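"""Simulate a single-cell T-cell landscape with a planted reactive state.

The generator plants a marker program: a chosen set of genes is shifted
upward (here by 2 log2 units) in one transcriptional state only, mimicking
an exhausted, tumor-reactive cluster among bystander states.
"""

import reactsig as rs

design = rs.ScDesign(n_genes=500, n_cells=600, n_states=4, n_signature_genes=40, seed=7)
expr, ann = rs.gen_sc_dataset(design)

print(f"expression matrix: {expr.shape[0]} genes x {expr.shape[1]} cells ({expr.scale})")
print(f"states: {sorted(ann.states().unique())}, reactive = {ann.truth['reactive_state']}")
print(f"cells per state:\n{ann.states().value_counts().sort_index().to_string()}")
print(f"planted marker genes: {len(ann.truth['planted_genes'])} "
      f"(first 5: {ann.truth['planted_genes'][:5]})")
# The planted genes are the ground truth every downstream recovery test uses.
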