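"""Rank genes by stepwise elimination and pick the minimal reference set.

The worst (highest-M) gene is removed and M recomputed until two genes
remain — the recommended, undiscriminated best pair.  The pairwise
variation V(n, n+1) between normalization factors with n and n+1 genes then
says whether adding more reference genes is worthwhile (threshold 0.15).
"""

import refstab as rs

# one gene is given a condition-effect ramp up to 1.5 cycles: an unstable gene
table, efficiencies, truth = rs.simulate(
    rs.default_study_config(seed=1, unstable_gene="GAPDH")
)
filtered, _ = rs.qc_filter(table)
rq = rs.to_relative_quantities(filtered, efficiencies)

trace = rs.rank_genes(rq)
print("eliminated (worst first):", " -> ".join(trace.eliminated))
print("recommended pair:", " + ".join(trace.final_pair))

vseries = rs.pairwise_variation_series(rq, trace, threshold=0.15)
for n, v in vseries.entries:
    print(f"V({n},{n + 1}) = {v:.4f}")
print("recommended number of reference genes:", vseries.recommended_n)

v_worst, ok = rs.worst_pair_check(rq, [g for g in rq.genes if g != "GAPDH"])
print(f"worst stable pair V = {v_worst:.4f} ({'passes' if ok else 'fails'} 0.15)")
# The injected unstable gene should fall first, and with the stable rest of
# the panel V(2,3) sits well under 0.15: two reference genes suffice.
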