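"""Labeled dissimilarity matrices and rating-table aggregation.

The central container is :class:`DissimilarityMatrix`: a square, symmetric,
nonnegative matrix over uniquely labeled items, with a zero diagonal.  All
downstream stages (Gromov-Wasserstein alignment, representational similarity
analysis, embedding) consume this type.  Group-average matrices are built from
long-format rating tables (one row per rated pair per rater or trial) by
pooling all ratings for each unordered pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DissimilarityMatrix",
    "RatingTable",
    "from_ratings",
    "normalize",
    "read_matrix_csv",
    "write_matrix_csv",
]

_SYMMETRY_TOL = 1e-9

RATING_COLUMNS = ("item_a", "item_b", "rating", "rater")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric nonnegative matrix over labeled items.

    Parameters
    ----------
    labels
        Ordered unique item identifiers.
    values
        ``n x n`` nonnegative array; symmetric to 1e-9, zero diagonal.
    normalized
        True once entries have been rescaled into ``[0, 1]`` with max 1
        (see :func:`normalize`).
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    normalized: bool = False

    def __post_init__(self) -> None:
        labels = tuple(str(lab) for lab in self.labels)
        object.__setattr__(self, "labels", labels)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"matrix must be square, got shape {values.shape}")
        n = values.shape[0]
        if n != len(labels):
            raise ValueError(
                f"{len(labels)} labels for a {n}x{n} matrix"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate labels: {dupes}")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix entries must be finite")
        asym = np.abs(values - values.T).max(initial=0.0)
        if asym > _SYMMETRY_TOL:
            raise ValueError(
                f"matrix is asymmetric: max |D - D.T| = {asym:.3g} exceeds {_SYMMETRY_TOL}"
            )
        values = (values + values.T) / 2.0
        if np.any(np.diag(values) != 0.0):
            raise ValueError("diagonal entries must be exactly 0")
        if values.min(initial=0.0) < 0:
            raise ValueError("entries must be nonnegative")
        if self.normalized:
            mx = values.max(initial=0.0)
            if mx > 0 and abs(mx - 1.0) > 1e-12:
                raise ValueError(
                    f"normalized matrix must have max entry 1, got {mx}"
                )
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def n_items(self) -> int:
        return len(self.labels)

    def permuted(self, perm: Sequence[int]) -> "DissimilarityMatrix":
        """Relabel items: new index ``perm[i]`` receives old item ``i``."""
        perm = np.asarray(perm, dtype=int)
        n = self.n_items
        if sorted(perm.tolist()) != list(range(n)):
            raise ValueError("perm must be a permutation of 0..n-1")
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        values = self.values[np.ix_(inv, inv)]
        labels = tuple(self.labels[i] for i in inv)
        return DissimilarityMatrix(labels, values, normalized=self.normalized)


@dataclass(frozen=True)
class RatingTable:
    """Long-format pairwise similarity ratings.

    One row per (item pair, rater-or-trial); ratings live on a bounded
    discrete or continuous scale ``[0, scale_max]`` (0 = identical,
    scale_max = maximally different).
    """

    data: pd.DataFrame = field(repr=False)
    scale_max: float = 7.0

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in RATING_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"rating table missing columns: {missing}")
        ratings = df["rating"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ratings)):
            raise ValueError("ratings must be finite")
        bad = (ratings < 0) | (ratings > self.scale_max)
        if np.any(bad):
            worst = ratings[bad][0]
            raise ValueError(
                f"rating {worst} outside scale [0, {self.scale_max}]"
            )

    @classmethod
    def from_records(
        cls, rows: Sequence[tuple], scale_max: float = 7.0
    ) -> "RatingTable":
        df = pd.DataFrame(rows, columns=list(RATING_COLUMNS))
        return cls(df, scale_max=scale_max)


def from_ratings(
    table: RatingTable,
    scale_max: float | None = None,
    labels: Sequence[str] | None = None,
) -> DissimilarityMatrix:
    """Group-average dissimilarity matrix from a rating table.

    Entry ``(i, j)`` is the plain mean of every rating for the unordered pair
    ``{i, j}``, pooled across raters/trials and across both row orderings.
    The diagonal is forced to zero regardless of any same-item ratings.

    Parameters
    ----------
    table
        Long-format ratings.
    scale_max
        Overrides the table's declared scale bound when given.
    labels
        Item order for the output.  Defaults to sorted order of all items
        appearing in the table.
    """
    df = table.data
    bound = table.scale_max if scale_max is None else float(scale_max)
    ratings = df["rating"].to_numpy(dtype=float)
    if np.any((ratings < 0) | (ratings > bound)):
        bad = ratings[(ratings < 0) | (ratings > bound)][0]
        raise ValueError(f"rating {bad} outside scale [0, {bound}]")

    a = df["item_a"].astype(str).to_numpy()
    b = df["item_b"].astype(str).to_numpy()
    if labels is None:
        labels = sorted(set(a) | set(b))
    labels = [str(lab) for lab in labels]
    index = {lab: i for i, lab in enumerate(labels)}
    unknown = (set(a) | set(b)) - set(labels)
    if unknown:
        raise ValueError(f"items not in label list: {sorted(unknown)}")

    n = len(labels)
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    ia = np.fromiter((index[x] for x in a), dtype=int, count=len(a))
    ib = np.fromiter((index[x] for x in b), dtype=int, count=len(b))
    # pool both orderings into the unordered pair
    lo, hi = np.minimum(ia, ib), np.maximum(ia, ib)
    np.add.at(total, (lo, hi), ratings)
    np.add.at(count, (lo, hi), 1)

    iu, ju = np.triu_indices(n, k=1)
    missing = count[iu, ju] == 0
    if np.any(missing):
        k = int(np.argmax(missing))
        raise ValueError(
            f"no rating for pair ({labels[iu[k]]}, {labels[ju[k]]})"
        )
    values = np.zeros((n, n))
    values[iu, ju] = total[iu, ju] / count[iu, ju]
    values[ju, iu] = values[iu, ju]
    return DissimilarityMatrix(tuple(labels), values, normalized=False)


def normalize(D: DissimilarityMatrix) -> DissimilarityMatrix:
    """Rescale entries into ``[0, 1]`` by dividing by the maximum entry.

    Idempotent; an all-zero matrix is returned unchanged (flagged
    normalized).  Rank order of entries is preserved.
    """
    mx = D.values.max(initial=0.0)
    if mx == 0.0:
        return replace(D, normalized=True)
    return DissimilarityMatrix(D.labels, D.values / mx, normalized=True)


def write_matrix_csv(D: DissimilarityMatrix, path: str | Path) -> None:
    """Write as CSV: header row of labels, then n rows of n floats."""
    df = pd.DataFrame(D.values, columns=list(D.labels))
    df.to_csv(path, index=False, float_format="%.17g")


def read_matrix_csv(path: str | Path) -> DissimilarityMatrix:
    """Read a matrix CSV written by :func:`write_matrix_csv`.

    Raises ``ValueError`` for non-square bodies, non-numeric fields,
    duplicate labels, or asymmetry beyond tolerance.
    """
    import csv as _csv

    with open(path, newline="") as fh:
        labels = next(_csv.reader(fh))
    labels = [lab.strip() for lab in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels in {path}: {dupes}")
    df = pd.read_csv(path, header=0, dtype=str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"non-square matrix in {path}: {df.shape[0]} rows x {df.shape[1]} columns"
        )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in {path}: {exc}") from None
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > _SYMMETRY_TOL:
        raise ValueError(
            f"asymmetric matrix in {path}: max |D - D.T| = {asym:.3g}"
        )
    # a written normalized matrix has max exactly 1; infer the flag from that
    normalized = abs(values.max(initial=0.0) - 1.0) <= 1e-12
    return DissimilarityMatrix(tuple(labels), values, normalized=normalized)
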