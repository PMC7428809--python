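"""Spatial clustering of mutator-fixed crypts.

Two crypts "agree" if both or neither have the mutator phenotype fixed.
When crypts are small enough to turn over, mutator crypts spread by
fission, so nearby crypts agree more than distant ones; pooling pairs
by exact hex lattice distance exposes the clonal footprint.
"""

import pandas as pd

from cryptsim import SimulationParams, run_replicates
from cryptsim.stats import mutator_agreement_by_distance

params = SimulationParams(grid_rows=4, grid_cols=4, crypt_size=4,
                          tsg_mutation_rate=0.0,  # no endpoint: full horizon
                          deleterious_fraction=0.5, max_days=15000.0)
results = run_replicates(params, 10, base_seed=3)

counts: dict[int, float] = {}
pairs: dict[int, int] = {}
for r in results:
    snap = r.final_tissue_snapshot
    if len(snap) < 2:
        continue
    for _, row in mutator_agreement_by_distance(snap).iterrows():
        d = int(row["distance_class"])
        pairs[d] = pairs.get(d, 0) + int(row["n_pairs"])
        counts[d] = counts.get(d, 0.0) + row["agreement"] * row["n_pairs"]

print("distance  pairs  agreement")
for d in sorted(pairs):
    print(f"{d:8d} {pairs[d]:6d} {counts[d] / pairs[d]:10.3f}")
print("\nAgreement well above 0.5 reflects fission-driven clonal expansion "
      "of\nmutator crypts; it is highest for adjacent crypts (the sparse "
      "longest\ndistance classes are noisy).")
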