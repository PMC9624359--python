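"""Reproduction driver for the packaged reference study.

Regenerates, from the packaged arenas and observed paths alone: the
distance and rank matrices, all LMRFT paths (3 agents x 4 levels), all
SMRFT paths (started at each agent's first observed food), the full
strategy-identification grid in both modes, and a comparison report
against the packaged expected values with per-item pass/fail.

The whole pipeline is deterministic.  Items marked failing in the report
are so in the shipped package as well: the printed identification grids
of the reference study are not reproducible from its printed inputs (see
docs/methods.md), while every path-construction item passes.
"""

from __future__ import annotations

import json
from pathlib import Path

from .fixtures import load_expected, load_fixture
from .foraging import DEFAULT_LEVELS, DEFAULT_STEPS, lmrft_path, smrft_path
from .geometry import distance_matrix, rank_matrix
from .io import write_matrix_csv, write_path_json
from .matching import match_strategy
from .radial import relative_min
from .structmetric import structural_distance

__all__ = ["reproduce_paper"]

ABS_TOL = 2e-3  # quantities recomputed from 3-decimal printed coordinates


def _item(name: str, computed, expected, ok: bool) -> dict:
    return {"item": name, "computed": computed, "expected": expected,
            "pass": bool(ok)}


def reproduce_paper(output_dir: str | Path) -> dict:
    """Run the full reference pipeline into ``output_dir``; return the
    comparison report (also written as ``report.json``)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    expected = load_expected()
    items: list[dict] = []

    v, w = load_fixture("example4_vectors")
    d4 = structural_distance(v, w)
    items.append(_item("example4_distance", d4, expected["example4_distance"],
                       abs(d4 - expected["example4_distance"]) <= 1e-5))

    toy = load_fixture("example1_toy")
    Dtoy = distance_matrix(toy)
    rm = relative_min(4, set(toy.labels), 3, Dtoy).value  # center q
    items.append(_item("example1_relmin_q_k3", rm,
                       expected["example1_relmin_q_k3"],
                       rm == expected["example1_relmin_q_k3"]))

    domains = {a: load_fixture(f"table1_animal{a}") for a in (1, 2, 3)}
    observed = {a: load_fixture(f"table4_observed{a}") for a in (1, 2, 3)}
    matrices = {}
    for a, dom in domains.items():
        D = distance_matrix(dom)
        matrices[a] = D
        write_matrix_csv(D, out / f"distances_animal{a}.csv")
        write_matrix_csv(rank_matrix(D), out / f"ranks_animal{a}.csv")

    d114 = matrices[1].dist(1, 14)
    items.append(_item("animal1_d_1_14", d114, expected["animal1_d_1_14"],
                       abs(d114 - expected["animal1_d_1_14"]) <= ABS_TOL))

    # modelled paths, both modes, all levels
    lmrft_paths: dict[int, dict[int, object]] = {}
    smrft_paths: dict[int, dict[int, object]] = {}
    for a, dom in domains.items():
        lmrft_paths[a], smrft_paths[a] = {}, {}
        for k in DEFAULT_LEVELS:
            lp = lmrft_path(dom, k, DEFAULT_STEPS, animal=f"a{a}",
                            D=matrices[a])
            sp = smrft_path(dom, observed[a].labels[0], k, DEFAULT_STEPS,
                            animal=f"a{a}", D=matrices[a])
            lmrft_paths[a][k] = lp
            smrft_paths[a][k] = sp
            write_path_json(lp, out / f"lmrft_animal{a}_level{k}.json")
            write_path_json(sp, out / f"smrft_animal{a}_level{k}.json")
            exp_seq = expected["lmrft_paths"][str(a)][str(k)]
            items.append(_item(f"lmrft_labels_animal{a}_level{k}",
                               list(lp.labels), exp_seq,
                               list(lp.labels) == exp_seq))

    p14 = lmrft_paths[1][4]
    items.append(_item("lmrft_animal1_level4_first_targets",
                       list(p14.labels[:5]),
                       expected["lmrft_animal1_level4_first_targets"],
                       list(p14.labels[:5])
                       == expected["lmrft_animal1_level4_first_targets"]))
    exp_sc = expected["lmrft_animal1_level4_first_scores"]
    items.append(_item("lmrft_animal1_level4_first_scores",
                       list(p14.scores[:2]), exp_sc,
                       all(abs(c - e) <= ABS_TOL
                           for c, e in zip(p14.scores[:2], exp_sc))))

    # identification grids
    grids = {"lmrft": {}, "smrft": {}}
    for a in (1, 2, 3):
        for mode, paths in (("lmrft", lmrft_paths[a]), ("smrft", smrft_paths[a])):
            m = match_strategy(observed[a], paths)
            grids[mode][a] = m
            exp_grid = expected[f"grid_{mode}"][str(a)]
            for k in DEFAULT_LEVELS:
                c, e = m.distances[k], exp_grid[str(k)]
                items.append(_item(f"grid_{mode}_animal{a}_level{k}", c, e,
                                   abs(c - e) <= ABS_TOL))
            stated = expected[f"stated_levels_{mode}"][str(a)]
            items.append(_item(f"selected_level_{mode}_animal{a}",
                               m.selected_level, stated,
                               m.selected_level == stated))

    report = {
        "items": items,
        "n_pass": sum(i["pass"] for i in items),
        "n_fail": sum(not i["pass"] for i in items),
        "grids": {mode: {str(a): grids[mode][a].to_dict()
                         for a in (1, 2, 3)} for mode in grids},
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
        fh.write("\n")
    return report
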