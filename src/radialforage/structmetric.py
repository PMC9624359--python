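"""Structural metric on strictly ascending vectors, and the path embedding.

The metric compares two strictly increasing real sequences ``v`` (length
``m``) and ``w`` (length ``n``) through their internal increment structure
rather than entrywise differences, so the lengths need not agree:

    d(v, w) = 1/2 * (||Δv|| + ||Δw||) - ||Δz||

where ``Δu`` is the vector of consecutive differences of ``u``, ``||.||``
the Euclidean norm, and ``z`` the *common parts* of ``v`` and ``w`` — the
sorted, deduplicated entries of either vector lying inside the overlap
window ``[max(v_1, w_1), min(v_m, w_n)]``.  Empty or singleton difference
vectors contribute norm 0.

A foraging path enters this domain through its cumulative leg distances
(by default with a leading 0, so that the compared paths share an origin).
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np

from .errors import InvalidInputError
from .foraging import ForagingPath

__all__ = [
    "as_ascending",
    "common_parts",
    "structural_distance",
    "path_to_ascending",
]

Parse = Literal["half_sum", "root_mean"]


def as_ascending(entries: Sequence[float]) -> np.ndarray:
    """Validate and return a strictly ascending vector as a float array."""
    v = np.asarray(entries, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise InvalidInputError("ascending vector must be 1-D and nonempty")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("ascending vector entries must be finite")
    if v.size > 1 and not np.all(np.diff(v) > 0):
        raise InvalidInputError("entries must be strictly increasing")
    return v


def common_parts(v: Sequence[float], w: Sequence[float]) -> np.ndarray:
    """Sorted, deduplicated entries of either vector inside the overlap
    window ``[max(v_1, w_1), min(v_m, w_n)]``; empty when the window is
    void."""
    v = as_ascending(v)
    w = as_ascending(w)
    lo, hi = max(v[0], w[0]), min(v[-1], w[-1])
    merged = np.union1d(v, w)
    return merged[(merged >= lo) & (merged <= hi)]


def _diff_norm(u: np.ndarray) -> float:
    if u.size < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(u)))


def structural_distance(
    v: Sequence[float], w: Sequence[float], *, parse: Parse = "half_sum"
) -> float:
    """Structural distance between two strictly ascending vectors.

    ``parse`` selects the aggregation of the two own-increment terms:
    ``"half_sum"`` (the default, ``(||Δv|| + ||Δw||)/2 - ||Δz||``,
    validated by the worked reference example) or the ``"root_mean"``
    variant ``sqrt((||Δv||² + ||Δw||²)/2) - ||Δz||``, kept available for
    sensitivity checks.
    """
    v = as_ascending(v)
    w = as_ascending(w)
    z = common_parts(v, w)
    if parse == "half_sum":
        return 0.5 * (_diff_norm(v) + _diff_norm(w)) - _diff_norm(z)
    if parse == "root_mean":
        rm = np.sqrt(0.5 * (_diff_norm(v) ** 2 + _diff_norm(w) ** 2))
        return float(rm - _diff_norm(z))
    raise InvalidInputError(f"unknown parse {parse!r}")


def path_to_ascending(
    path: ForagingPath, *, leading_zero: bool = True
) -> np.ndarray:
    """Embed a foraging path as its cumulative leg-distance vector.

    With ``leading_zero`` (the default) the vector is
    ``(0, d_1, d_1 + d_2, ...)`` — one entry per visited food; without it
    the leading origin entry is dropped.  Strict ascent is guaranteed by
    the positivity of the legs.
    """
    cum = np.concatenate([[0.0], np.cumsum(path.legs)])
    return cum if leading_zero else cum[1:]
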