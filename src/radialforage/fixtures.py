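"""Packaged reference fixtures: arenas, observed paths and worked examples.

The packaged data are the printed inputs of the reference study: three
20-food 2-D arenas (``table1_animal1..3``), the three recorded
("hypothetically real") foraging paths whose legs are data rather than
geometry (``table4_observed1..3``), a four-point toy metric space
(``example1_toy``, with foods x, y, p, q relabeled 1..4) and the worked
ascending-vector pair of the structural-metric example
(``example4_vectors``).
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .foraging import ForagingPath
from .geometry import FoodDomain
from .io import path_from_dict, read_foods_csv

__all__ = ["FIXTURE_NAMES", "load_fixture", "load_expected"]

FIXTURE_NAMES = (
    "table1_animal1",
    "table1_animal2",
    "table1_animal3",
    "table4_observed1",
    "table4_observed2",
    "table4_observed3",
    "example1_toy",
    "example4_vectors",
)

#: Labels of the Example-1 toy points in the order x, y, p, q.
EXAMPLE1_LABELS = {"x": 1, "y": 2, "p": 3, "q": 4}


def _resource(name: str):
    return resources.files("radialforage") / "fixtures" / name


def load_fixture(
    name: str,
) -> FoodDomain | ForagingPath | tuple[np.ndarray, np.ndarray]:
    """Load a packaged fixture by name.

    Returns a :class:`FoodDomain` for arenas, a :class:`ForagingPath` for
    observed paths, and an ``(v, w)`` pair of ascending vectors for
    ``example4_vectors``.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if name.startswith("table1_") or name == "example1_toy":
        with resources.as_file(_resource(name + ".csv")) as p:
            return read_foods_csv(p)
    if name.startswith("table4_"):
        data = json.loads(_resource(name + ".json").read_text("utf-8"))
        return path_from_dict(data)
    data = json.loads(_resource("example4_vectors.json").read_text("utf-8"))
    return np.asarray(data["v"], float), np.asarray(data["w"], float)


def load_expected() -> dict:
    """Expected values decoded from the printed reference tables, used by
    the reproduction driver's comparison report."""
    return json.loads(
        (_resource("expected") / "reference.json").read_text("utf-8")
    )
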