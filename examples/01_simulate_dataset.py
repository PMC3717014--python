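"""Generate a study-shaped synthetic Cq dataset.

Seven candidate reference genes across seven condition groups (naive plus
six post-surgery timepoints) of three subjects each, in triplicate wells.
"""

import refstab as rs

config = rs.default_study_config(seed=1)
table, efficiencies, truth = rs.simulate(config)

print(table)
print("genes:", ", ".join(table.genes))
print("conditions:", ", ".join(table.conditions().unique()))
print(truth.to_string(index=False))
# 441 measurements = 7 genes x 21 samples x 3 technical replicates; every
# gene is truly stable here (no condition effects), so downstream stability
# statistics should validate the whole panel.
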