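"""LMRFT and SMRFT path construction with domain depletion."""

import math

import numpy as np
import pytest

import radialforage as rf
from radialforage.errors import ConfigurationError, InvalidInputError
from radialforage.fixtures import load_expected

# toy labels: x=1, y=2, p=3, q=4


class TestLmrft:
    def test_toy_step_tie_resolves_to_lowest_label(self, toy_D):
        # k=3 scores: x=sqrt(10), y=sqrt(13), p=sqrt(10), q=sqrt(34);
        # x and p tie, the lower label (x) wins
        target, score = rf.lmrft_step({1, 2, 3, 4}, 3, toy_D)
        assert target == 1
        assert score == pytest.approx(math.sqrt(10))

    def test_toy_two_step_path(self, toy_domain):
        path = rf.lmrft_path(toy_domain, 3, 2)
        assert path.labels == (1, 3)  # x then p

    def test_level_one_is_degenerate_zero_scores(self, toy_D):
        target, score = rf.lmrft_step({2, 3, 4}, 1, toy_D)
        assert (target, score) == (2, 0.0)

    def test_animal1_level4_first_five_targets_and_scores(self, animal1):
        path = rf.lmrft_path(animal1, 4, 14)
        assert path.labels[:5] == (16, 7, 17, 8, 18)
        assert path.scores[0] == pytest.approx(1.4707, abs=2e-3)
        assert path.scores[1] == pytest.approx(1.7417, abs=2e-3)

    @pytest.mark.parametrize("animal", [1, 2, 3])
    @pytest.mark.parametrize("level", [2, 3, 4, 5])
    def test_reference_arena_paths_match_decoded_tables(self, animal, level):
        """All 12 printed optimal-path label sequences reproduce exactly."""
        dom = rf.load_fixture(f"table1_animal{animal}")
        expected = load_expected()["lmrft_paths"][str(animal)][str(level)]
        assert list(rf.lmrft_path(dom, level, 14).labels) == expected

    def test_single_food_path(self, toy_domain):
        path = rf.lmrft_path(toy_domain, 3, 1)
        assert len(path.labels) == 1 and path.legs == ()

    def test_configuration_errors(self, toy_domain):
        with pytest.raises(ConfigurationError):
            rf.lmrft_path(toy_domain, 3, 5)  # N > |domain|
        with pytest.raises(ConfigurationError):
            rf.lmrft_path(toy_domain, 4, 2)  # k > |domain| - N + 1

    def test_relabeling_equivariance(self, random_domain):
        # seed chosen tie-free: mutual k-th-nearest pairs share an exact
        # score, and only tie-breaks are label-dependent
        dom = random_domain(n=9, seed=1)
        perm = {l: ((l + 3) % 9) + 1 for l in dom.labels}
        relabeled = rf.FoodDomain(
            tuple(perm[l] for l in dom.labels), dom.points
        )
        p1 = rf.lmrft_path(dom, 3, 6)
        p2 = rf.lmrft_path(relabeled, 3, 6)
        assert tuple(perm[l] for l in p1.labels) == p2.labels


class TestSmrft:
    def test_toy_step_from_q(self, toy_D):
        # candidates {x,y,p}; scores sqrt(13), sqrt(13), sqrt(10) -> p
        target, score = rf.smrft_step({1, 2, 3}, 4, 3, toy_D)
        assert target == 3
        assert score == pytest.approx(math.sqrt(10))

    def test_toy_two_step_path(self, toy_domain):
        assert rf.smrft_path(toy_domain, 4, 3, 2).labels == (4, 3)

    def test_rank_one_ball_takes_nearer_point(self, toy_D):
        # from x, ball of rank 1 within {y,p}: p is nearer
        target, _ = rf.smrft_step({2, 3}, 1, 1, toy_D)
        assert target == 3

    def test_score_tie_broken_by_proximity_before_label(self):
        # foods 2 and 3 tie on the k=2 objective (d(2,3) both ways);
        # the forager at food 1 is strictly nearer to the higher label 3
        dom = rf.FoodDomain.from_coords(
            {1: (0.5, 3.0), 2: (-1.0, 0.0), 3: (1.0, 0.0), 4: (0.0, 9.0)}
        )
        D = rf.distance_matrix(dom)
        target, _ = rf.smrft_step({2, 3}, 1, 2, D)
        assert target == 3

    def test_start_must_be_in_domain(self, toy_domain):
        with pytest.raises(InvalidInputError):
            rf.smrft_path(toy_domain, 9, 2, 2)

    def test_targets_lie_in_predecessor_ball(self, animal1, animal1_D):
        path = rf.smrft_path(animal1, 7, 3, 14)
        remaining = set(animal1.labels) - {7}
        current = 7
        for nxt in path.labels[1:]:
            ball = rf.radial_ball(current, remaining, 3, animal1_D)
            assert nxt in ball
            remaining.discard(nxt)
            current = nxt

    def test_deterministic_regeneration(self, random_domain):
        dom = random_domain(n=20, seed=5)
        p = rf.smrft_path(dom, dom.labels[0], 4, 14)
        again = rf.smrft_path(dom, p.labels[0], 4, 14)
        assert p.labels == again.labels and p.legs == again.legs


class TestPathInvariants:
    @pytest.mark.parametrize("mode", ["lmrft", "smrft"])
    def test_no_repeats_and_leg_count(self, random_domain, mode):
        dom = random_domain(n=14, seed=19)
        if mode == "lmrft":
            path = rf.lmrft_path(dom, 3, 10)
        else:
            path = rf.smrft_path(dom, dom.labels[2], 3, 10)
        assert len(set(path.labels)) == len(path.labels) == 10
        assert len(path.legs) == 9 and all(g > 0 for g in path.legs)

    def test_legs_equal_euclidean_distances(self, animal1, animal1_D):
        path = rf.lmrft_path(animal1, 2, 14)
        for (a, b), leg in zip(zip(path.labels, path.labels[1:]), path.legs):
            assert leg == animal1_D.dist(a, b)

    def test_scores_match_brute_force_recomputation(self, random_domain):
        """Replay each step against an explicit k-th order statistic."""
        dom = random_domain(n=10, seed=2)
        D = rf.distance_matrix(dom)
        k = 3
        path = rf.lmrft_path(dom, k, 7)
        remaining = set(dom.labels)
        for label, score in zip(path.labels, path.scores):
            brute = min(
                sorted(D.dist(e, y) for y in remaining)[k - 1]
                for e in remaining
            )
            assert score == brute
            remaining.discard(label)

    def test_path_validation(self):
        with pytest.raises(InvalidInputError):
            rf.ForagingPath(None, "lmrft", 2, None, (1, 2, 1), (1.0, 1.0))
        with pytest.raises(InvalidInputError):
            rf.ForagingPath(None, "observed", None, None, (1, 2), (-1.0,))
        with pytest.raises(InvalidInputError):
            rf.ForagingPath(None, "walk", None, None, (1,), ())
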