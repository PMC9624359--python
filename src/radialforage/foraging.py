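"""LMRFT and SMRFT optimal foraging paths over a depleting food domain.

Both techniques pick, at every step, the remaining food whose k-th least
distance *within the remaining domain* is minimal — a density-driven
objective: the preferred target sits where at least ``k`` foods (itself
included) crowd inside the smallest possible radius.  They differ in the
candidate set:

* **LMRFT** (long-term-memory radial foraging): the forager has global
  knowledge of the remaining domain, so every uneaten food is a candidate.
* **SMRFT** (short-term-memory radial foraging): candidates are confined to
  the radial ball of level ``k`` around the forager's current position;
  the starting food is empirical (for identification runs, the first food
  of the observed path).

After each step the eaten food is removed: ``S_i = S_{i-1} - {x_i}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import AbstractSet

import numpy as np

from .errors import ConfigurationError, InvalidInputError, RadialLevelError
from .geometry import DistanceMatrix, FoodDomain, distance_matrix
from .radial import radial_ball, relative_min

__all__ = [
    "ForagingPath",
    "lmrft_step",
    "lmrft_path",
    "smrft_step",
    "smrft_path",
    "DEFAULT_LEVELS",
    "DEFAULT_STEPS",
]

#: Radial levels and step count of the reference study configuration.
DEFAULT_LEVELS: tuple[int, ...] = (2, 3, 4, 5)
DEFAULT_STEPS: int = 14


@dataclass(frozen=True)
class ForagingPath:
    """An ordered traversal of distinct foods with per-leg distances.

    ``mode`` is ``"lmrft"`` or ``"smrft"`` for modelled optimal paths
    (``legs`` are then the Euclidean distances between consecutive foods)
    and ``"observed"`` for empirical paths, whose legs are data in their
    own right.  ``scores`` optionally records the per-step chosen
    objective value (the winning k-th relative minimum).
    """

    animal: str | None
    mode: str
    level: int | None
    start: int | None
    labels: tuple[int, ...]
    legs: tuple[float, ...]
    scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(int(l) for l in self.labels))
        object.__setattr__(self, "legs", tuple(float(g) for g in self.legs))
        if self.scores is not None:
            object.__setattr__(
                self, "scores", tuple(float(s) for s in self.scores)
            )
        if self.mode not in ("lmrft", "smrft", "observed"):
            raise InvalidInputError(f"unknown path mode {self.mode!r}")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidInputError("path labels must be distinct")
        if len(self.legs) != max(len(self.labels) - 1, 0):
            raise InvalidInputError("need exactly one leg per label pair")
        if any(g <= 0 for g in self.legs):
            raise InvalidInputError("all legs must be positive")

    def __len__(self) -> int:
        return len(self.labels)


def _kth_scores(
    D: DistanceMatrix, candidates: list[int], subset: list[int], k: int
) -> np.ndarray:
    """k-th least distance from each candidate to the members of subset."""
    if k < 1:
        raise InvalidInputError(f"radial level must be >= 1, got {k}")
    if k > len(subset):
        raise RadialLevelError(
            f"radial level {k} exceeds subset size {len(subset)}"
        )
    rows = [D._i(e) for e in candidates]
    cols = [D._i(y) for y in subset]
    sub = D.values[np.ix_(rows, cols)]
    return np.sort(sub, axis=1)[:, k - 1]


def lmrft_step(
    subset: AbstractSet[int], k: int, D: DistanceMatrix
) -> tuple[int, float]:
    """One LMRFT choice: the food minimizing the k-th least distance to the
    remaining domain, ties resolved to the lowest label.

    Returns ``(target, score)`` where ``score`` is the winning k-th
    relative minimum.
    """
    members = sorted(subset)
    scores = _kth_scores(D, members, members, k)
    i = int(np.lexsort((members, scores))[0])
    return members[i], float(scores[i])


def smrft_step(
    subset: AbstractSet[int], current: int, k: int, D: DistanceMatrix
) -> tuple[int, float]:
    """One SMRFT choice: same objective as LMRFT but candidates restricted
    to the level-k radial ball around the forager's current position.

    Score ties are resolved by proximity to ``current``, then lowest label.
    """
    if current in subset:
        raise InvalidInputError("current position must already be eaten")
    members = sorted(subset)
    candidates = sorted(radial_ball(current, subset, k, D))
    scores = _kth_scores(D, candidates, members, k)
    prox = np.array([D.dist(current, e) for e in candidates])
    i = int(np.lexsort((candidates, prox, scores))[0])
    return candidates[i], float(scores[i])


def _check_config(domain: FoodDomain, k: int, N: int) -> None:
    if not 1 <= N <= len(domain):
        raise ConfigurationError(
            f"step count N={N} must be within 1..{len(domain)}"
        )
    if not 1 <= k <= len(domain) - N + 1:
        raise ConfigurationError(
            f"radial level k={k} must be within 1..{len(domain) - N + 1} "
            f"for N={N} steps on {len(domain)} foods"
        )


def lmrft_path(
    domain: FoodDomain,
    k: int,
    N: int,
    *,
    animal: str | None = None,
    D: DistanceMatrix | None = None,
) -> ForagingPath:
    """LMRFT-optimal path of ``N`` foods on ``domain`` at radial level ``k``.

    Iterates :func:`lmrft_step`, removing each eaten food, and records the
    Euclidean legs between consecutive targets plus the per-step scores.
    """
    _check_config(domain, k, N)
    if D is None:
        D = distance_matrix(domain)
    subset = set(domain.labels)
    labels: list[int] = []
    scores: list[float] = []
    for _ in range(N):
        target, score = lmrft_step(subset, k, D)
        labels.append(target)
        scores.append(score)
        subset.discard(target)
    legs = [D.dist(a, b) for a, b in zip(labels, labels[1:])]
    return ForagingPath(
        animal, "lmrft", k, None, tuple(labels), tuple(legs), tuple(scores)
    )


def smrft_path(
    domain: FoodDomain,
    start: int,
    k: int,
    N: int,
    *,
    animal: str | None = None,
    D: DistanceMatrix | None = None,
) -> ForagingPath:
    """SMRFT-optimal path of ``N`` foods starting at the empirical food
    ``start``, at radial level ``k``."""
    if start not in domain:
        raise InvalidInputError(f"start label {start} not in domain")
    _check_config(domain, k, N)
    if D is None:
        D = distance_matrix(domain)
    subset = set(domain.labels) - {start}
    labels = [start]
    scores: list[float] = []
    current = start
    for _ in range(N - 1):
        target, score = smrft_step(subset, current, k, D)
        labels.append(target)
        scores.append(score)
        subset.discard(target)
        current = target
    legs = [D.dist(a, b) for a, b in zip(labels, labels[1:])]
    return ForagingPath(
        animal, "smrft", k, start, tuple(labels), tuple(legs), tuple(scores)
    )
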