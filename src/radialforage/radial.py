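"""k-th relative minima and radial balls.

The *relative minimum* ``min_x^S(k)`` is the k-th least value in the
multiset of distances from a center ``x`` to the members of a food subset
``S`` — when ``x`` itself belongs to ``S`` its self-distance 0 occupies
rank 1.  The *radial ball* ``B_x^S(k)`` is the closed ball around ``x``
with that radius, intersected with ``S``.  The radial level ``k`` is the
model's handle on an animal's perceptive capability: a level-k forager
"sees" as far as its k-th nearest remaining food.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable

import numpy as np

from .errors import InvalidInputError, RadialLevelError
from .geometry import DistanceMatrix

__all__ = ["RadialQuery", "relative_min", "radial_ball"]


@dataclass(frozen=True)
class RadialQuery:
    """Result of a relative-minimum query.

    ``value`` is the k-th least distance from ``center`` to ``subset`` and
    ``achiever`` the label attaining it (ties resolved to the lowest label).
    """

    center: int
    subset: frozenset[int]
    k: int
    value: float
    achiever: int


def _sorted_pairs(center: int, subset: Iterable[int], D: DistanceMatrix):
    labels = sorted(subset)
    dists = np.array([D.dist(center, y) for y in labels])
    order = np.lexsort((labels, dists))
    return [(float(dists[i]), labels[i]) for i in order]


def relative_min(
    center: int, subset: AbstractSet[int], k: int, D: DistanceMatrix
) -> RadialQuery:
    """k-th least distance from ``center`` to the members of ``subset``.

    The center need not belong to the subset; when it does, its
    self-distance 0 counts at rank 1.
    """
    if k < 1:
        raise InvalidInputError(f"radial level must be >= 1, got {k}")
    if not subset:
        raise InvalidInputError("subset must be nonempty")
    if k > len(subset):
        raise RadialLevelError(
            f"radial level {k} exceeds subset size {len(subset)}"
        )
    value, achiever = _sorted_pairs(center, subset, D)[k - 1]
    return RadialQuery(center, frozenset(subset), k, value, achiever)


def radial_ball(
    center: int, subset: AbstractSet[int], k: int, D: DistanceMatrix
) -> set[int]:
    """Members of ``subset`` within the closed ball of radius
    ``relative_min(center, subset, k).value`` around ``center``.

    Borders are included, so the ball always holds at least ``k`` members
    and balls are nested in ``k``.
    """
    r = relative_min(center, subset, k, D).value
    return {y for y in subset if D.dist(center, y) <= r}
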