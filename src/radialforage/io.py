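"""Plain-text readers and writers: foods CSV, matrix CSV, path JSON/CSV.

Foods CSV: header ``label,x1,...,xd``, one row per food, UTF-8, ``.``
decimal.  Path JSON: ``{"animal", "mode", "level", "start", "labels",
"legs", "scores"}``.  Distance and rank matrices are written as CSV with
the label sequence as both header row and first column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .foraging import ForagingPath
from .geometry import DistanceMatrix, FoodDomain, RankMatrix

__all__ = [
    "read_foods_csv",
    "write_foods_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "read_path_json",
    "write_path_json",
    "write_path_csv",
]


def read_foods_csv(path: str | Path) -> FoodDomain:
    df = pd.read_csv(path)
    cols = list(df.columns)
    if not cols or cols[0] != "label":
        raise InvalidInputError(f"{path}: first column must be 'label'")
    expect = [f"x{i}" for i in range(1, len(cols))]
    if cols[1:] != expect:
        raise InvalidInputError(f"{path}: coordinate columns must be {expect}")
    labels = tuple(int(l) for l in df["label"])
    return FoodDomain(labels, df[cols[1:]].to_numpy(dtype=float))


def write_foods_csv(domain: FoodDomain, path: str | Path) -> None:
    cols = {"label": list(domain.labels)}
    for j in range(domain.d):
        cols[f"x{j + 1}"] = domain.points[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_matrix_csv(
    matrix: DistanceMatrix | RankMatrix, path: str | Path
) -> None:
    values = matrix.values if isinstance(matrix, DistanceMatrix) else matrix.ranks
    df = pd.DataFrame(values, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path, index_label="label")


def read_matrix_csv(path: str | Path, *, ranks: bool = False):
    df = pd.read_csv(path, index_col="label")
    labels = tuple(int(l) for l in df.index)
    if ranks:
        return RankMatrix(labels, df.to_numpy(dtype=int))
    return DistanceMatrix(labels, df.to_numpy(dtype=float))


def path_to_dict(p: ForagingPath) -> dict:
    return {
        "animal": p.animal,
        "mode": p.mode,
        "level": p.level,
        "start": p.start,
        "labels": list(p.labels),
        "legs": list(p.legs),
        "scores": None if p.scores is None else list(p.scores),
    }


def path_from_dict(d: dict) -> ForagingPath:
    return ForagingPath(
        d.get("animal"),
        d["mode"],
        d.get("level"),
        d.get("start"),
        tuple(d["labels"]),
        tuple(d["legs"]),
        None if d.get("scores") is None else tuple(d["scores"]),
    )


def read_path_json(path: str | Path) -> ForagingPath:
    with open(path, encoding="utf-8") as fh:
        return path_from_dict(json.load(fh))


def write_path_json(p: ForagingPath, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(path_to_dict(p), fh, indent=1)
        fh.write("\n")


def write_path_csv(p: ForagingPath, path: str | Path) -> None:
    """CSV variant: columns step,label,leg (leg is the distance *into* the
    step's food; empty for the first step)."""
    legs = [np.nan] + list(p.legs)
    pd.DataFrame(
        {"step": range(1, len(p.labels) + 1), "label": p.labels, "leg": legs}
    ).to_csv(path, index=False)
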