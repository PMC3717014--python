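"""QC-filter a Cq table and convert it to relative quantities.

Each gene's Cq values are rescaled to the gene's lowest Cq and converted to
linear scale with its amplification efficiency: RQ = (1+E)^(anchor - Cq).
"""

import refstab as rs

table, efficiencies, _ = rs.simulate(rs.default_study_config(seed=1))
filtered, qc_log = rs.qc_filter(table, max_cq=30.0, max_replicate_spread=0.5)
print(f"QC removed {len(qc_log)} of {table.n_measurements} wells")

rq = rs.to_relative_quantities(filtered, efficiencies)
print(f"RQ matrix: {len(rq.genes)} genes x {len(rq.samples)} samples")
print("per-gene anchors (lowest Cq):")
print(rq.anchors.round(2).to_string())
print("first samples:")
print(rq.values.iloc[:, :3].round(3).to_string())
# All RQ values are in (0, 1]: the sample at a gene's anchor well scores 1,
# every extra cycle divides the quantity by (1+E).
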