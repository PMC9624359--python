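"""Food domains, Euclidean distance matrices, rank matrices and relative order.

A *food domain* is a finite set of labeled points in ``R^d`` (``d >= 2``):
the locations of placed food items in a foraging arena, or feature vectors
("intangible locations") describing distinct foods.  All downstream
machinery — radial minima, optimal path construction, strategy matching —
consumes only the pairwise Euclidean distance matrix of a domain and the
per-row ordinal ranks derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InvalidInputError

__all__ = [
    "FoodDomain",
    "DistanceMatrix",
    "RankMatrix",
    "distance_matrix",
    "rank_matrix",
    "relative_order",
]


@dataclass(frozen=True)
class FoodDomain:
    """Labeled points in ``R^d``; the mutable-by-copy set that depletes as
    foods are eaten.

    Parameters
    ----------
    labels
        Distinct positive integer labels, one per food.
    points
        Array of shape ``(n, d)`` with ``d >= 2``; row ``i`` is the
        coordinate vector of ``labels[i]``.  All entries must be finite.
    """

    labels: tuple[int, ...]
    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", tuple(int(l) for l in self.labels))
        if pts.ndim != 2 or pts.shape[1] < 2:
            raise InvalidInputError(
                f"points must be (n, d) with d >= 2, got shape {pts.shape}"
            )
        if len(self.labels) != pts.shape[0]:
            raise InvalidInputError("one coordinate vector per label required")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidInputError("labels must be unique")
        if any(l < 1 for l in self.labels):
            raise InvalidInputError("labels must be positive integers")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("all coordinates must be finite")

    @classmethod
    def from_coords(cls, coords: Mapping[int, Sequence[float]]) -> "FoodDomain":
        labels = tuple(coords)
        return cls(labels, np.array([coords[l] for l in labels], dtype=float))

    @property
    def d(self) -> int:
        """Dimensionality of the coordinate space."""
        return self.points.shape[1]

    @property
    def coords(self) -> dict[int, np.ndarray]:
        """Mapping label -> coordinate vector (copies)."""
        return {l: self.points[i].copy() for i, l in enumerate(self.labels)}

    def coord(self, label: int) -> np.ndarray:
        try:
            return self.points[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown food label {label}") from None

    def remove(self, label: int) -> "FoodDomain":
        """Domain with one food eaten; the original is left untouched."""
        if label not in self.labels:
            raise KeyError(f"unknown food label {label}")
        keep = [i for i, l in enumerate(self.labels) if l != label]
        return FoodDomain(tuple(self.labels[i] for i in keep), self.points[keep])

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.labels


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise Euclidean distances between the foods of a domain."""

    labels: tuple[int, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(int(l) for l in self.labels))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise InvalidInputError("values must be square and match labels")
        object.__setattr__(
            self, "_index", {l: i for i, l in enumerate(self.labels)}
        )

    def _i(self, label: int) -> int:
        try:
            return self._index[label]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown food label {label}") from None

    def dist(self, a: int, b: int) -> float:
        return float(self.values[self._i(a), self._i(b)])

    def row(self, label: int) -> np.ndarray:
        return self.values[self._i(label)]


@dataclass(frozen=True)
class RankMatrix:
    """Per-row ordinal ranks (1 = least) of a distance matrix."""

    labels: tuple[int, ...]
    ranks: np.ndarray = field(repr=False)


def distance_matrix(domain: FoodDomain) -> DistanceMatrix:
    """Euclidean distance matrix of a food domain.

    Distances are computed in double precision from the stored coordinates;
    the diagonal is exactly zero and the matrix exactly symmetric.
    """
    if len(domain) == 0:
        raise InvalidInputError("domain must be nonempty")
    values = cdist(domain.points, domain.points)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(domain.labels, values)


def rank_matrix(D: DistanceMatrix) -> RankMatrix:
    """Ordinal rank of every entry within its row (1 = least).

    Ties are broken by ascending column label, so each row is always a
    permutation of ``1..n``.  For domains without exactly coincident foods
    the diagonal (self-distance 0) always ranks 1.
    """
    n = len(D.labels)
    labels_arr = np.asarray(D.labels)
    ranks = np.empty((n, n), dtype=int)
    for i in range(n):
        order = np.lexsort((labels_arr, D.values[i]))
        ranks[i, order] = np.arange(1, n + 1)
    return RankMatrix(D.labels, ranks)


def relative_order(
    x: int, y: int, z: int, D: DistanceMatrix
) -> Literal["<", "=", ">"]:
    """Compare foods ``y`` and ``z`` by their distance from ``x``.

    Returns ``"<"`` when ``d(x, y) < d(x, z)``, ``"="`` on exact equality
    and ``">"`` otherwise.  For any fixed ``x`` this relation is a total
    preorder on the domain, consistent with row ``x`` of the rank matrix.
    """
    dy, dz = D.dist(x, y), D.dist(x, z)
    if dy < dz:
        return "<"
    if dy == dz:
        return "="
    return ">"
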