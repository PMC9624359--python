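"""Foraging-strategy identification by structural-distance matching.

Given an observed path and modelled optimal paths at several radial
levels, the agent's radial level is identified as the argmin of the
structural distances between the observed path and each modelled path,
both embedded as cumulative-distance ascending vectors.  Observed paths
carry their recorded legs verbatim; modelled paths use Euclidean legs
recomputed from the domain geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import InvalidInputError
from .foraging import ForagingPath, lmrft_path, smrft_path
from .geometry import FoodDomain, distance_matrix
from .structmetric import Parse, path_to_ascending, structural_distance

__all__ = ["StrategyMatch", "match_strategy", "match_all"]


@dataclass(frozen=True)
class StrategyMatch:
    """Per-level structural distances and the selected (argmin) level."""

    animal: str | None
    mode: str
    distances: dict[int, float]
    selected_level: int

    def to_dict(self) -> dict:
        return {
            "animal": self.animal,
            "mode": self.mode,
            "distances": {str(k): v for k, v in self.distances.items()},
            "selected_level": self.selected_level,
        }


def match_strategy(
    observed: ForagingPath,
    modelled: Mapping[int, ForagingPath],
    *,
    parse: Parse = "half_sum",
    leading_zero: bool = True,
) -> StrategyMatch:
    """Identify the radial level whose modelled path is structurally
    closest to the observed path.

    Ties in the argmin are resolved to the lowest level.
    """
    if not modelled:
        raise InvalidInputError("modelled path mapping must be nonempty")
    ov = path_to_ascending(observed, leading_zero=leading_zero)
    distances = {
        int(k): structural_distance(
            ov, path_to_ascending(p, leading_zero=leading_zero), parse=parse
        )
        for k, p in sorted(modelled.items())
    }
    selected = min(distances, key=lambda k: (distances[k], k))
    modes = {p.mode for p in modelled.values()}
    mode = modes.pop() if len(modes) == 1 else "mixed"
    return StrategyMatch(observed.animal, mode, distances, selected)


def match_all(
    observed_paths: Mapping[str, ForagingPath],
    domains: Mapping[str, FoodDomain],
    modes: Iterable[str] = ("lmrft", "smrft"),
    levels: Iterable[int] = (2, 3, 4, 5),
    N: int = 14,
    *,
    parse: Parse = "half_sum",
    leading_zero: bool = True,
) -> list[StrategyMatch]:
    """Batch identification across agents and foraging modes.

    Builds modelled paths per mode and level on each agent's own domain
    (SMRFT starts at the first food of that agent's observed path) and
    applies :func:`match_strategy`.
    """
    levels = sorted(set(int(k) for k in levels))
    if not levels:
        raise InvalidInputError("levels must be nonempty")
    modes = list(modes)
    unknown = set(modes) - {"lmrft", "smrft"}
    if unknown:
        raise InvalidInputError(f"unknown modes {sorted(unknown)}")
    results: list[StrategyMatch] = []
    for animal, observed in observed_paths.items():
        domain = domains[animal]
        D = distance_matrix(domain)
        for mode in modes:
            modelled: dict[int, ForagingPath] = {}
            for k in levels:
                if mode == "lmrft":
                    modelled[k] = lmrft_path(domain, k, N, animal=animal, D=D)
                else:
                    modelled[k] = smrft_path(
                        domain, observed.labels[0], k, N, animal=animal, D=D
                    )
            results.append(
                match_strategy(
                    observed, modelled, parse=parse, leading_zero=leading_zero
                )
            )
    return results
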