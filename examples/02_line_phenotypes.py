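"""Aggregate seed records from replicate harvests into line phenotypes.

Builds a toy dataset of two lines with two replicate harvests each,
deliberately unbalanced in seed number, and shows that the final value
per line is the unweighted average of the replicate means — a replicate
with 10x the seeds does not get 10x the weight.
"""

import numpy as np
import pandas as pd

from seedscan import aggregate_records

rng = np.random.default_rng(0)
rows = []
for line, base in [("L1", 0.115), ("L2", 0.135)]:
    for rep, (shift, n) in {"r1": (-0.004, 40), "r2": (+0.004, 400)}.items():
        for _ in range(n):
            area = base + shift + rng.normal(0, 0.008)
            rows.append({
                "line_id": line, "replicate_id": rep,
                "area_mm2": area, "major_mm": 0.55 + rng.normal(0, 0.02),
                "minor_mm": 0.30 + rng.normal(0, 0.01),
            })
records = pd.DataFrame(rows)

final = aggregate_records(records, mode="replicate-mean")
pooled = aggregate_records(records, mode="pooled")
print("replicate-mean aggregation (each harvest counts equally):")
print(final.to_string(index=False))
print("\npooled aggregation (each seed counts equally):")
print(pooled.to_string(index=False))
# The replicate-mean area lands midway between the two harvest means;
# the pooled value is pulled toward the larger harvest.
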