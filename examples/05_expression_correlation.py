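"""Parent-retrocopy expression correlation and testis bias.

Simulates an FPKM matrix with planted correlation structure and tissue
specificity, then runs the correlation and specificity machinery on it.
"""

import numpy as np

from retrokit import expression_analysis as ea
from retrokit import synthetic_data as sd

cfg = sd.SimulationConfig(
    n_contigs=3, contig_length=110_000, n_genes=24, n_retro_events=48,
    n_dna_duplications=0, specific_fraction=0.0,
    parent_correlation_weights=(0.2, 0.4, 0.4), include_zero_pair=False,
    seed=31)
genome, genes = sd.simulate_genome(cfg)
_, truth, _, _ = sd.plant_retrocopies(genome, genes, cfg)
matrix, etruth = sd.simulate_expression(truth, genes, cfg)

pairs = [(t.event_id, t.parent_gene_id) for t in truth if t.kind == "retro"]
results = ea.pair_correlations(matrix, pairs)
cats = {}
for r in results:
    cats[r.category] = cats.get(r.category, 0) + 1
print(f"{len(results)} parent-retrocopy pairs over "
      f"{matrix.values.shape[1]} samples")
print("categories:", cats)
print("planted mixture was 20% strong / 40% weak / 40% independent; the")
print("category fractions recover it through Pearson R + BH-FDR gating.\n")

ys = [ea.fisher_y(r.r) for r in results if abs(r.r) < 1]
ks = np.random.default_rng(0).uniform(0, 3, len(ys))  # independent mock ages
reg = ea.regress_y_on_ks(ks, ys)
print(f"regression of Y = ln((1+R)/(1-R)) on independent Ks: "
      f"R2 = {reg['r_squared']:.3f}, p = {reg['p_value']:.2f}")
print("R2 near zero: correlation with the parent does not decay with age")
print("when the ages are unrelated to the planted structure.")
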