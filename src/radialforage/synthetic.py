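"""Seeded generators for food domains and synthetic observed paths.

Food positions are drawn i.i.d. from a multivariate normal centred at the
origin — the study's stand-in for a patchy but unimodal food landscape.
The default covariance ``[[18, 5], [5, 9]]`` matches the sample moments of
the reference 2-D arenas (x-variance ≈ 17, y-variance ≈ 9, covariance ≈ 6)
and is fully configurable.

Synthetic observed paths are modelled optimal paths with optional
perturbations applied to what an identification pipeline actually
consumes: the label order (random adjacent swaps) and the leg lengths
(multiplicative log-normal noise).  Leg noise, not coordinate noise, is
the right corruption model here because empirical path legs are recorded
data, decoupled from the arena geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .foraging import DEFAULT_LEVELS, DEFAULT_STEPS, ForagingPath, lmrft_path, smrft_path
from .geometry import FoodDomain, distance_matrix

__all__ = ["SimulationConfig", "sample_food_positions", "synth_observed_path"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic foraging study.

    Defaults mirror the reference conditions: 20 foods in 2-D, four radial
    levels 2..5, 14 foraging steps.
    """

    n_foods: int = 20
    dims: int = 2
    mean: tuple[float, ...] = (0.0, 0.0)
    covariance: tuple[tuple[float, ...], ...] = ((18.0, 5.0), (5.0, 9.0))
    seed: int = 0
    levels: tuple[int, ...] = DEFAULT_LEVELS
    steps: int = DEFAULT_STEPS

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        mean = np.asarray(self.mean, dtype=float)
        if mean.shape != (self.dims,):
            raise InvalidInputError("mean length must equal dims")
        if cov.shape != (self.dims, self.dims):
            raise InvalidInputError("covariance must be dims x dims")
        if not np.allclose(cov, cov.T):
            raise InvalidInputError("covariance must be symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise InvalidInputError("covariance must be positive definite")
        if not 1 <= self.steps <= self.n_foods:
            raise InvalidInputError("need n_foods >= steps >= 1")


def sample_food_positions(config: SimulationConfig) -> FoodDomain:
    """Draw a labeled food domain from the configured multivariate normal.

    Identical seeds yield identical domains.
    """
    rng = np.random.default_rng(config.seed)
    pts = rng.multivariate_normal(
        np.asarray(config.mean, float),
        np.asarray(config.covariance, float),
        size=config.n_foods,
        method="cholesky",
    )
    return FoodDomain(tuple(range(1, config.n_foods + 1)), pts)


def synth_observed_path(
    domain: FoodDomain,
    mode: str,
    level: int,
    N: int,
    leg_noise_sd: float = 0.0,
    swap_rate: float = 0.0,
    seed: int = 0,
    *,
    start: int | None = None,
    animal: str | None = None,
) -> ForagingPath:
    """Synthetic "observed" path: a modelled optimal path, optionally
    corrupted.

    With ``swap_rate > 0`` each adjacent label pair is swapped with that
    probability (one left-to-right pass); legs are then recomputed from
    the geometry of the swapped sequence.  With ``leg_noise_sd > 0`` each
    leg is multiplied by an independent log-normal factor
    ``exp(N(0, leg_noise_sd))``.  At zero noise and zero swap rate the
    result carries exactly the modelled labels and legs, recorded with
    mode ``"observed"``.
    """
    if leg_noise_sd < 0:
        raise InvalidInputError("leg_noise_sd must be >= 0")
    if not 0 <= swap_rate <= 1:
        raise InvalidInputError("swap_rate must be within [0, 1]")
    D = distance_matrix(domain)
    if mode == "lmrft":
        base = lmrft_path(domain, level, N, animal=animal, D=D)
    elif mode == "smrft":
        if start is None:
            start = min(domain.labels)
        base = smrft_path(domain, start, level, N, animal=animal, D=D)
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    labels = list(base.labels)
    if swap_rate > 0:
        for i in range(len(labels) - 1):
            if rng.random() < swap_rate:
                labels[i], labels[i + 1] = labels[i + 1], labels[i]
    legs = np.array([D.dist(a, b) for a, b in zip(labels, labels[1:])])
    if leg_noise_sd > 0:
        legs = legs * np.exp(rng.normal(0.0, leg_noise_sd, size=legs.size))
    return ForagingPath(
        animal, "observed", None, None, tuple(labels), tuple(legs), None
    )
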