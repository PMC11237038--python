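"""High correlation without item-level correspondence.

Two structures share a coarse category skeleton but the fine within-category
structure of the second is resampled independently.  Supervised RSA
(Spearman on corresponding entries) stays high, yet unsupervised alignment
can only match items at chance — the dissociation that correlation alone
cannot detect.
"""

import numpy as np

from gwalign import normalize, rsa_spearman, select_optimum, sweep
from gwalign.synthetic import make_category_pair

for resample in (False, True):
    pair = make_category_pair(resample_fine=resample, seed=0)
    src, tgt = normalize(pair.source), normalize(pair.target)

    # reindex the target to the source's label order for the supervised view
    order = [tgt.labels.index(lab) for lab in src.labels]
    perm = np.empty(tgt.n_items, dtype=int)
    perm[order] = np.arange(tgt.n_items)
    rho = rsa_spearman(src, tgt.permuted(perm))

    result = sweep(
        src, tgt, n_trials=12, seed=1,
        labels_for_eval=(src.labels, tgt.labels),
    )
    rate = select_optimum(result).matching_rate

    kind = "resampled fine structure" if resample else "matched fine structure"
    print(
        f"{kind}: Spearman rho = {rho:.2f}, "
        f"matching rate = {rate:.1f}% (chance {100 / src.n_items:.1f}%)"
    )
# With matched fine structure both numbers are high.  With resampled fine
# structure the correlation stays around 0.7 while matching collapses to
# chance: the structures are correlated but not alignable item-by-item.
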