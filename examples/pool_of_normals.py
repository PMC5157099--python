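"""Build a pool-of-normals database and pick the best reference for a tumor.

Demonstrates GC normalization, target weighting (unstable targets are
down-weighted), the low-coverage mask and PCA-based best-normal selection.
"""

import numpy as np

from allelecn.coverage import build_normaldb, compute_log_ratios, gc_normalize, select_best_normal
from allelecn.simulate import simulate_coverage, simulate_genome

truth = simulate_genome(n_segments=25, n_targets=1200, purity=0.7, target_ploidy=2.8, seed=17)
tumor, _, normals = simulate_coverage(truth, depth=100.0, seed=17, n_normals=5)

gc = truth.targets["gc"].to_numpy()
tumor_n = gc_normalize(tumor, gc)
pool = np.stack([gc_normalize(normals[:, j], gc) for j in range(normals.shape[1])], axis=1)

db = build_normaldb(pool, truth.targets["chrom"].to_numpy())
print(f"pool of {db.n_normals} normals on {len(db.weights)} targets")
print(f"  retained targets after low-coverage mask: {int(db.mask.sum())}")
print(f"  target weight range: {db.weights.min():.2f} .. {db.weights.max():.2f} (mean 1)")

ids, reference = select_best_normal(tumor_n, db)
print(f"  best process-matched normal: {ids[0]}")

profile = compute_log_ratios(tumor_n, reference, db, truth.targets)
r = profile.r[profile.mask]
print(f"  log-ratio profile: {len(r)} targets, SD {r.std():.2f}")

# weights feed the weighted segmentation; a weight well below 1 marks a
# target whose coverage is unstable across normals (mappability, CNVs).
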