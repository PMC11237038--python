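"""Synthetic dissimilarity-structure pairs with known ground truth.

Every downstream stage (rating aggregation, Gromov-Wasserstein alignment,
matching-rate evaluation, RSA, embedding) is exercised on generated data
whose true item correspondence is known, emulating the statistical shape of
group-averaged human similarity judgments (0-7 discrete ratings averaged
over many raters), trial-averaged LLM ratings, and — crucially — structure
pairs whose coarse category layout agrees while the fine within-category
structure does or does not correspond.  The latter reproduces the central
dissociation this toolkit exists to expose: two structures can correlate
highly (supervised RSA) while unsupervised alignment matches items only at
chance.

Default geometry: items are points in Euclidean space, so base matrices are
honest metrics; category structures place items around separated category
centroids, and "resampling the fine structure" redraws the within-category
offsets of the target independently while keeping the category skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import DissimilarityMatrix, RatingTable

__all__ = [
    "SyntheticPair",
    "sample_structure",
    "make_pair",
    "make_category_pair",
    "simulate_rater_panel",
    "simulate_llm_trials",
]


@dataclass(frozen=True)
class SyntheticPair:
    """Two dissimilarity matrices plus the ground-truth correspondence.

    ``true_permutation[i]`` is the target index holding source item i; with
    zero noise and no fine-structure resampling the target equals the source
    under this permutation exactly.  Labels are shared between the two
    matrices, so label-based matching-rate evaluation applies directly.
    """

    source: DissimilarityMatrix
    target: DissimilarityMatrix
    true_permutation: tuple[int, ...]
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        perm = tuple(int(i) for i in self.true_permutation)
        n = self.source.n_items
        if sorted(perm) != list(range(n)) or self.target.n_items != n:
            raise ValueError("true_permutation must be a bijection on 0..n-1")
        object.__setattr__(self, "true_permutation", perm)


def _labels(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"item{str(i).zfill(width)}" for i in range(n))


def sample_structure(
    n: int, dim: int = 3, seed: int = 0
) -> tuple[np.ndarray, DissimilarityMatrix]:
    """I.i.d. standard-normal point cloud and its Euclidean distance matrix."""
    if n < 3 or dim < 1:
        raise ValueError("need n >= 3 and dim >= 1")
    rng = np.random.default_rng(seed)
    points = rng.standard_normal((n, dim))
    D = DissimilarityMatrix(_labels(n), squareform(pdist(points)))
    return points, D


def _perturb(values: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise on off-diagonals; re-symmetrized by averaging
    the two perturbed triangles, clipped at 0, zero diagonal."""
    n = values.shape[0]
    noisy = values + rng.normal(0.0, noise_sd, size=(n, n))
    noisy = (noisy + noisy.T) / 2.0
    noisy = np.clip(noisy, 0.0, None)
    np.fill_diagonal(noisy, 0.0)
    return noisy


def make_pair(
    base: DissimilarityMatrix,
    noise_sd: float = 0.0,
    seed: int = 0,
    permute: bool = True,
) -> SyntheticPair:
    """Noisy, optionally relabeled copy of a base structure.

    The target is the base with Gaussian noise (sd ``noise_sd``) added to
    the off-diagonals and, when ``permute``, its items re-indexed by a
    random permutation.  Labels travel with the items, so the pair is
    exactly what an unsupervised aligner should re-match.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = base.n_items
    noisy = _perturb(base.values, noise_sd, rng) if noise_sd > 0 else base.values
    target = DissimilarityMatrix(base.labels, noisy)
    perm = rng.permutation(n) if permute else np.arange(n)
    target = target.permuted(perm)
    return SyntheticPair(
        source=base,
        target=target,
        true_permutation=tuple(int(x) for x in perm),
        params={"noise_sd": noise_sd, "seed": seed, "permute": permute, "n": n},
    )


def make_category_pair(
    n_categories: int = 2,
    items_per_category: int = 31,
    between_sep: float = 1.5,
    within_scale: float = 0.25,
    resample_fine: bool = False,
    noise_sd: float = 0.0,
    dim: int = 3,
    seed: int = 0,
) -> SyntheticPair:
    """Structure pair with shared coarse categories and controllable
    fine-item correspondence.

    Items sit around ``n_categories`` centroids (i.i.d. normal with sd
    ``between_sep``) with within-category offsets of sd ``within_scale``.
    With ``resample_fine=False`` the target reuses the source's offsets, so
    the two structures agree item-by-item.  With ``resample_fine=True`` the
    target's offsets are redrawn independently: the category skeleton — and
    hence the supervised correlation — survives, but no fine-item
    correspondence exists, so unsupervised matching can only succeed at the
    category level.  The target is always randomly re-indexed.

    Defaults (2 categories x 31 items = 62 items) give a structure with a
    coarse two-cluster skeleton and rich fine structure, the regime where
    supervised correlation and unsupervised matching dissociate.
    """
    if n_categories < 2 or items_per_category < 2:
        raise ValueError("need n_categories >= 2 and items_per_category >= 2")
    rng = np.random.default_rng(seed)
    n = n_categories * items_per_category
    if n_categories <= dim:
        # randomly oriented orthogonal directions: every pair of centroids
        # sits at distance exactly between_sep
        basis = np.linalg.qr(rng.standard_normal((dim, dim)))[0][:, :n_categories]
        centroids = basis.T * (between_sep / np.sqrt(2.0))
    else:
        centroids = rng.standard_normal((n_categories, dim))
        d = pdist(centroids)
        centroids *= between_sep / np.sqrt((d**2).mean())
    cat = np.repeat(np.arange(n_categories), items_per_category)

    offsets_src = rng.standard_normal((n, dim)) * within_scale
    points_src = centroids[cat] + offsets_src
    if resample_fine:
        offsets_tgt = rng.standard_normal((n, dim)) * within_scale
    else:
        offsets_tgt = offsets_src
    points_tgt = centroids[cat] + offsets_tgt

    labels = _labels(n)
    source = DissimilarityMatrix(labels, squareform(pdist(points_src)))
    tgt_values = squareform(pdist(points_tgt))
    if noise_sd > 0:
        tgt_values = _perturb(tgt_values, noise_sd, rng)
    target = DissimilarityMatrix(labels, tgt_values)
    perm = rng.permutation(n)
    target = target.permuted(perm)
    return SyntheticPair(
        source=source,
        target=target,
        true_permutation=tuple(int(x) for x in perm),
        params={
            "n_categories": n_categories,
            "items_per_category": items_per_category,
            "between_sep": between_sep,
            "within_scale": within_scale,
            "resample_fine": resample_fine,
            "noise_sd": noise_sd,
            "dim": dim,
            "seed": seed,
            "category_of_item": tuple(int(c) for c in cat),
        },
    )


def simulate_rater_panel(
    base: DissimilarityMatrix,
    n_raters: int = 50,
    scale_max: float = 7.0,
    rater_noise_sd: float = 1.0,
    seed: int = 0,
) -> RatingTable:
    """Panel of discrete similarity judgments over all pairs of a structure.

    Each rater's rating for pair (i, j) is
    ``round(clip(scale_max * base_ij + noise, 0, scale_max))`` — an
    integer on the 0..scale_max scale, emulating judgments that are later
    group-averaged into a dissimilarity matrix.  ``base`` must be
    normalized so ``scale_max * base`` spans the rating scale.
    """
    if not base.normalized:
        raise ValueError("base matrix must be normalized (entries in [0, 1])")
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    rng = np.random.default_rng(seed)
    n = base.n_items
    iu, ju = np.triu_indices(n, k=1)
    ideal = scale_max * base.values[iu, ju]
    rows = []
    for r in range(n_raters):
        noise = rng.normal(0.0, rater_noise_sd, size=ideal.size)
        ratings = np.rint(np.clip(ideal + noise, 0.0, scale_max))
        for k in range(ideal.size):
            rows.append(
                (base.labels[iu[k]], base.labels[ju[k]], float(ratings[k]), f"rater{r}")
            )
    return RatingTable.from_records(rows, scale_max=scale_max)


def simulate_llm_trials(
    base: DissimilarityMatrix,
    n_trials: int = 5,
    trial_noise_sd: float = 0.3,
    scale_max: float = 7.0,
    seed: int = 0,
) -> DissimilarityMatrix:
    """Trial-averaged continuous ratings of a structure.

    Emulates querying a language model for real-valued 0..scale_max
    dissimilarity ratings of every pair and averaging over ``n_trials``
    independent trials (5 by default), each a noisy continuous readout of
    the underlying structure clipped to the scale.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    n = base.n_items
    scale = scale_max if base.normalized else 1.0
    ideal = scale * base.values
    acc = np.zeros((n, n))
    for _ in range(n_trials):
        noise = rng.normal(0.0, trial_noise_sd, size=(n, n))
        noise = (noise + noise.T) / 2.0
        trial = np.clip(ideal + noise, 0.0, scale_max if base.normalized else None)
        np.fill_diagonal(trial, 0.0)
        acc += trial
    return DissimilarityMatrix(base.labels, acc / n_trials)
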