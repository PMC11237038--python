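"""Post-alignment evaluation: label-based matching rate and supervised RSA.

The matching rate grades an (unsupervised) transport plan with external
labels: source item i "matches" when the argmax of its plan row lands on a
target item carrying the same label; the rate is the percentage of matched
source items.  Chance level for n distinct shared labels is 100/n.

Representational similarity analysis (RSA) is the conventional supervised
contrast: Spearman rank correlation between the strict upper triangles of
two dissimilarity matrices, assuming item correspondence by position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .alignment import TransportPlan
from .core import DissimilarityMatrix

__all__ = ["MatchingReport", "matching_rate", "rsa_spearman"]


@dataclass(frozen=True)
class MatchingReport:
    """Top-1 matching outcome of a transport plan against external labels."""

    matching_rate: float  # percentage in [0, 100]
    per_item_match: tuple[bool, ...]
    chance_level: float  # 100/n for distinct shared labels
    tie_flags: tuple[bool, ...]  # True where the row argmax was tied
    top_k_rates: dict[int, float] | None = None


def matching_rate(
    plan: TransportPlan,
    labels1: Sequence[str],
    labels2: Sequence[str],
    top_k: Sequence[int] | None = None,
) -> MatchingReport:
    """Percentage of source items whose plan-row argmax hits the same label.

    Ties in a row argmax break toward the smallest target index and are
    flagged (exact ties are measure-zero for strictly positive entropic
    plans but can occur for degenerate inputs).  Duplicate labels are
    permitted: a match requires label equality, not index equality.
    """
    G = plan.values
    n, m = G.shape
    if len(labels1) != n or len(labels2) != m:
        raise ValueError(
            f"label lengths ({len(labels1)}, {len(labels2)}) do not match "
            f"plan shape {G.shape}"
        )
    l1 = [str(x) for x in labels1]
    l2 = np.array([str(x) for x in labels2])
    best = np.argmax(G, axis=1)  # smallest index on ties
    row_max = G[np.arange(n), best]
    ties = tuple(bool(np.sum(G[i] == row_max[i]) > 1) for i in range(n))
    matches = tuple(bool(l2[best[i]] == l1[i]) for i in range(n))
    rate = 100.0 * sum(matches) / n

    top_k_rates = None
    if top_k:
        order = np.argsort(-G, axis=1, kind="stable")
        top_k_rates = {}
        for k in top_k:
            hits = sum(
                l1[i] in set(l2[order[i, :k]]) for i in range(n)
            )
            top_k_rates[int(k)] = 100.0 * hits / n
    return MatchingReport(
        matching_rate=rate,
        per_item_match=matches,
        chance_level=100.0 / n,
        tie_flags=ties,
        top_k_rates=top_k_rates,
    )


def rsa_spearman(D: DissimilarityMatrix, Dp: DissimilarityMatrix) -> float:
    """Spearman rho between the strict upper triangles of two matrices.

    This is the supervised comparison: it inherently assumes that item i of
    one matrix corresponds to item i of the other, so the label lists must
    agree in order.  Ties are handled by average (fractional) ranks.
    """
    if D.labels != Dp.labels:
        raise ValueError(
            "rsa_spearman assumes a label correspondence: label lists must "
            "be identical and in the same order"
        )
    n = D.n_items
    if n < 3:
        raise ValueError("need at least 3 items for a rank correlation")
    iu, ju = np.triu_indices(n, k=1)
    rho = stats.spearmanr(D.values[iu, ju], Dp.values[iu, ju]).statistic
    return float(rho)
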