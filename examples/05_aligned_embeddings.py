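"""Visualizable aligned embeddings via MDS and plan-guided Procrustes.

Embeds two corresponding structures in 3-D with metric MDS, aligns the
second onto the first with the orthogonal rotation derived from the optimal
transport plan, and reports how close each item lands to its true
counterpart relative to the other items.
"""

import numpy as np

from gwalign import mds_embed, normalize, procrustes_align, select_optimum, sweep
from gwalign.synthetic import make_pair, sample_structure

_, base = sample_structure(n=15, dim=3, seed=0)
base = normalize(base)
pair = make_pair(base, noise_sd=0.0, seed=1)

result = sweep(pair.source, pair.target, n_trials=15, seed=2)
opt = select_optimum(result)

X = mds_embed(pair.source, dim=3, seed=3)
Y = mds_embed(pair.target, dim=3, seed=3)
rot = procrustes_align(X, Y, opt.plan)

aligned = rot.aligned  # rotated target coordinates, items as columns
perm = np.array(pair.true_permutation)
dists = np.linalg.norm(X.coords[:, :, None] - aligned[:, None, :], axis=0)
counterpart_mask = np.zeros_like(dists, dtype=bool)
counterpart_mask[np.arange(15), perm] = True
to_counterpart = dists[counterpart_mask].mean()
to_others = dists[~counterpart_mask].mean()

print(f"MDS stress (source): {X.stress:.4f}")
print(f"rotation residual: {rot.residual:.3e}, det(Q) = {np.linalg.det(rot.Q):+.0f}")
print(f"mean distance to true counterpart: {to_counterpart:.3f}")
print(f"mean distance to non-counterparts: {to_others:.3f}")
# After rotation, each source point should sit much closer to its true
# counterpart than to unrelated items — the quantitative version of the
# "same items end up side by side" picture used for visual inspection.
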