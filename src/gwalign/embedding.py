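"""MDS embeddings and plan-guided orthogonal (Procrustes) alignment.

Dissimilarity matrices are embedded in low-dimensional space by metric MDS
(SMACOF).  Two embeddings X (d x n) and Y (d x m) are then superimposed for
visualization by the orthogonal matrix Q minimizing

    || X - Q Y G* ||_F^2

where G* is the optimal transport plan: Y G* is the plan-weighted
(barycentric) projection of the target points onto the source index, and the
minimizing Q comes from the SVD of X (Y G*)^T.  Labels play no role; the
correspondence is carried entirely by the plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import MDS

from .alignment import TransportPlan
from .core import DissimilarityMatrix

__all__ = ["EmbeddingSet", "RotationResult", "mds_embed", "procrustes_align"]


@dataclass(frozen=True)
class EmbeddingSet:
    """d-dimensional coordinates per item; columns of ``coords`` are items."""

    labels: tuple[str, ...]
    coords: np.ndarray = field(repr=False)  # d x n
    stress: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != len(self.labels):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def dim(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class RotationResult:
    """Orthogonal rotation aligning a target embedding onto a source one."""

    Q: np.ndarray = field(repr=False)  # d x d, orthogonal to 1e-8
    aligned: np.ndarray = field(repr=False)  # Q @ Y: rotated target coords
    residual: float  # Frobenius objective at the optimum


def mds_embed(
    D: DissimilarityMatrix,
    dim: int = 3,
    seed: int = 0,
    n_restarts: int = 8,
) -> EmbeddingSet:
    """Metric MDS (SMACOF) coordinates for a dissimilarity matrix.

    Runs ``n_restarts`` SMACOF starts and keeps the best-stress solution;
    deterministic given ``seed``.
    """
    n = D.n_items
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if dim >= n:
        raise ValueError(f"dim={dim} must be < number of items ({n})")
    mds = MDS(
        n_components=dim,
        metric_mds=True,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        random_state=seed,
        normalized_stress=False,
    )
    coords = mds.fit_transform(np.asarray(D.values))
    return EmbeddingSet(labels=D.labels, coords=coords.T, stress=float(mds.stress_))


def procrustes_align(
    X: EmbeddingSet, Y: EmbeddingSet, plan: TransportPlan
) -> RotationResult:
    """Best orthogonal rotation of Y onto X through a transport plan.

    The stored plan is (n source items) x (m target items); its transpose is
    the G* that right-multiplies Y's coordinate matrix.  Because a coupling
    with uniform marginals carries mass 1/n per source item, the barycentric
    projection Y G* is rescaled by n so projected points live on the scale of
    the original coordinates (the optimal Q itself is scale-invariant).

    Returns Q = U V^T from the SVD of X (Y G*)^T, the rotated target
    coordinates Q @ Y, and the Frobenius residual ||X - Q Y G*||_F of the
    scaled objective.  Reflections (det Q = -1) are permitted: Q is
    constrained to be orthogonal only.
    """
    if X.dim != Y.dim:
        raise ValueError(f"embedding dims differ: {X.dim} vs {Y.dim}")
    n, m = plan.shape
    if X.coords.shape[1] != n or Y.coords.shape[1] != m:
        raise ValueError(
            f"plan shape {plan.shape} does not match embeddings "
            f"({X.coords.shape[1]} source, {Y.coords.shape[1]} target items)"
        )
    # mass-scaled barycentric projection of Y onto the source index
    proj = Y.coords @ (plan.values.T * n)  # d x n
    M = X.coords @ proj.T
    U, _, Vt = np.linalg.svd(M)
    Q = U @ Vt
    residual = float(np.linalg.norm(X.coords - Q @ proj))
    return RotationResult(Q=Q, aligned=Q @ Y.coords, residual=residual)
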