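"""Soft boundary-aware scoring and entity matching."""

import itertools
import random

import pytest

from ccmer.evaluate import (
    corpus_soft_prf,
    filter_confusion,
    match_entities,
    soft_prf,
    soft_score,
)
from ccmer.resources import ContractError, EntityAnnotation, EntityClass


def ann(start, end, cls="WM"):
    return EntityAnnotation(start, end, EntityClass(cls))


class TestSoftScore:
    @pytest.mark.parametrize(
        "pred,expected",
        [
            (ann(5, 9), 1.0),  # exact boundaries and class
            (ann(6, 9), 0.8),  # start error only
            (ann(5, 8), 0.6),  # end error only
            (ann(6, 8), 0.4),  # both boundaries wrong
        ],
    )
    def test_lattice(self, pred, expected):
        assert soft_score(ann(5, 9), pred) == expected

    def test_start_errors_cost_less_than_end_errors(self):
        # a start-shifted 恩度 annotation outranks an end-shifted one
        gold = ann(2, 4)
        assert soft_score(gold, ann(3, 4)) > soft_score(gold, ann(2, 5))

    def test_antitone_in_boundary_errors(self):
        gold = ann(5, 9)
        scores = [
            soft_score(gold, ann(5, 9)),
            soft_score(gold, ann(6, 9)),
            soft_score(gold, ann(5, 8)),
            soft_score(gold, ann(6, 8)),
        ]
        assert scores == sorted(scores, reverse=True)
        assert set(scores) <= {1.0, 0.8, 0.6, 0.4}

    def test_class_mismatch_rejected(self):
        with pytest.raises(ContractError):
            soft_score(ann(5, 9, "WM"), ann(5, 9, "TCM"))

    def test_disjoint_spans_rejected(self):
        with pytest.raises(ContractError):
            soft_score(ann(0, 2), ann(5, 9))


def brute_force_best_assignment(gold, pred):
    """Oracle: maximize total overlap over all one-to-one assignments."""
    gold, pred = list(gold), list(pred)

    def overlap(g, p):
        if g.cls != p.cls:
            return 0
        return max(0, min(g.end, p.end) - max(g.start, p.start))

    best = 0
    k = min(len(gold), len(pred))
    for r in range(k + 1):
        for g_sub in itertools.permutations(gold, r):
            for p_sub in itertools.combinations(pred, r):
                total = sum(overlap(g, p) for g, p in zip(g_sub, p_sub))
                if all(overlap(g, p) > 0 for g, p in zip(g_sub, p_sub)):
                    best = max(best, total)
    return best


class TestMatchEntities:
    def test_identical_sets_pair_perfectly(self):
        gold = {ann(0, 2), ann(5, 9)}
        pairs, ug, up = match_entities(gold, set(gold))
        assert len(pairs) == 2 and not ug and not up

    def test_disjoint_sets_no_pairs(self):
        pairs, ug, up = match_entities({ann(0, 2)}, {ann(5, 9)})
        assert not pairs and len(ug) == 1 and len(up) == 1

    def test_larger_overlap_wins(self):
        gold = {ann(0, 10)}
        pred = {ann(0, 3), ann(4, 10)}
        pairs, _, up = match_entities(gold, pred)
        assert pairs == [(ann(0, 10), ann(4, 10))]
        assert up == [ann(0, 3)]

    def test_matches_overlap_maximizing_oracle(self):
        rng = random.Random(11)
        for _ in range(150):
            def spans(n):
                out, pos = [], 0
                for _ in range(n):
                    pos += rng.randint(0, 3)
                    length = rng.randint(1, 4)
                    out.append(
                        ann(pos, pos + length, rng.choice(["WM", "TCM"]))
                    )
                    pos += length
                return set(out)

            gold, pred = spans(rng.randint(0, 4)), spans(rng.randint(0, 4))
            pairs, _, _ = match_entities(gold, pred)
            greedy_total = sum(
                min(g.end, p.end) - max(g.start, p.start) for g, p in pairs
            )
            assert greedy_total == brute_force_best_assignment(gold, pred)

    def test_overlapping_gold_rejected(self):
        with pytest.raises(ContractError):
            match_entities({ann(0, 3), ann(2, 5)}, set())


class TestSoftPrf:
    def test_exact_single_pair(self):
        rep = soft_prf({ann(5, 9)}, {ann(5, 9)})
        assert (rep.precision, rep.recall, rep.f_measure) == (1.0, 1.0, 1.0)

    def test_two_golds_one_start_shifted_pred(self):
        # soft score 0.8 over 1 prediction and 2 golds: P=0.8, R=0.4, F=8/15
        rep = soft_prf({ann(5, 9), ann(20, 24)}, {ann(6, 9)})
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(0.4)
        assert rep.f_measure == pytest.approx(8 / 15)

    def test_empty_predictions(self):
        with pytest.warns(UserWarning):
            rep = soft_prf({ann(5, 9)}, set())
        assert (rep.precision, rep.recall, rep.f_measure) == (0.0, 0.0, 0.0)

    def test_wrong_class_scores_zero(self):
        rep = soft_prf({ann(5, 9, "WM")}, {ann(5, 9, "TCM")})
        assert rep.f_measure == 0.0
        assert rep.per_class["WM"].recall == 0.0

    def test_swapping_gold_and_pred_swaps_p_and_r(self):
        gold = {ann(0, 4), ann(10, 14), ann(20, 22, "TCM")}
        pred = {ann(1, 4), ann(10, 13)}
        a = soft_prf(gold, pred)
        b = soft_prf(pred, gold)
        assert a.precision == pytest.approx(b.recall)
        assert a.recall == pytest.approx(b.precision)

    def test_soft_at_least_strict_precision(self):
        gold = {ann(0, 4), ann(10, 14)}
        pred = {ann(1, 4), ann(10, 14), ann(30, 33)}
        rep = soft_prf(gold, pred)
        strict = sum(1 for p in pred if p in gold) / len(pred)
        assert rep.precision >= strict

    def test_percent_rounding(self):
        rep = soft_prf({ann(5, 9), ann(20, 24)}, {ann(6, 9)})
        assert rep.round_percent(rep.f_measure) == 53.3

    def test_corpus_micro_average(self):
        golds = [{ann(5, 9)}, {ann(0, 2, "TCM")}, set()]
        preds = [{ann(6, 9)}, {ann(0, 2, "TCM")}, {ann(1, 3)}]
        rep = corpus_soft_prf(golds, preds)
        assert rep.precision == pytest.approx(1.8 / 3)
        assert rep.recall == pytest.approx(1.8 / 2)
        assert rep.per_class["TCM"].f_measure == pytest.approx(1.0)


class TestFilterConfusion:
    def test_perfect_predictions_diagonal(self):
        c = filter_confusion([True, False, True], [True, False, True])
        assert c == {"tp": 2, "tn": 1, "fp": 0, "fn": 0}

    def test_flipped_predictions_off_diagonal(self):
        c = filter_confusion([True, False], [False, True])
        assert c == {"tp": 0, "tn": 0, "fp": 1, "fn": 1}

    def test_counts_conserved(self):
        rng = random.Random(0)
        gold = [rng.random() < 0.5 for _ in range(100)]
        pred = [rng.random() < 0.5 for _ in range(100)]
        assert sum(filter_confusion(gold, pred).values()) == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            filter_confusion([True], [True, False])
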