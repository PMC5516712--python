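"""Soft boundary-aware scoring of medication entity predictions.

A matched same-class prediction earns partial credit from the five-value
lattice {1, 0.8, 0.6, 0.4, 0}: exact span 1; wrong start only 0.8; wrong
end only 0.6; both wrong 0.4; unmatched predictions and golds 0.  A correct
start is worth more than a correct end because a start-shifted annotation
like 静滴恩度 tagged from the verb onward is still clinically recoverable.

Soft precision divides the summed scores by the number of predicted
entities, soft recall by the number of gold entities, and F is their
harmonic mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .resources import ContractError, EntityAnnotation, EntityClass

SOFT_SCORES = (1.0, 0.8, 0.6, 0.4, 0.0)


def soft_score(gold: EntityAnnotation, pred: EntityAnnotation) -> float:
    """Score one matched (same-class, overlapping) gold/pred pair."""
    if gold.cls != pred.cls:
        raise ContractError("soft_score is defined for same-class pairs only")
    if not gold.overlaps(pred):
        raise ContractError("soft_score requires overlapping spans")
    start_ok = gold.start == pred.start
    end_ok = gold.end == pred.end
    if start_ok and end_ok:
        return 1.0
    if end_ok:
        return 0.8  # start-position error only
    if start_ok:
        return 0.6  # end-position error only
    return 0.4


def match_entities(
    gold: frozenset[EntityAnnotation] | set,
    pred: frozenset[EntityAnnotation] | set,
) -> tuple[list[tuple[EntityAnnotation, EntityAnnotation]], list[EntityAnnotation], list[EntityAnnotation]]:
    """Greedy one-to-one pairing of same-class overlapping entities.

    Pairs are taken in descending character overlap, ties broken by earlier
    gold start.  Returns (pairs, unmatched_gold, unmatched_pred).
    """
    _check_non_overlapping(gold, "gold")
    _check_non_overlapping(pred, "pred")
    candidates = []
    for g in gold:
        for p in pred:
            if g.cls == p.cls and g.overlaps(p):
                ov = min(g.end, p.end) - max(g.start, p.start)
                candidates.append((-ov, g.start, g.end, p.start, g, p))
    candidates.sort(key=lambda t: t[:4])
    pairs = []
    used_g: set[EntityAnnotation] = set()
    used_p: set[EntityAnnotation] = set()
    for *_, g, p in candidates:
        if g not in used_g and p not in used_p:
            pairs.append((g, p))
            used_g.add(g)
            used_p.add(p)
    unmatched_gold = sorted(set(gold) - used_g)
    unmatched_pred = sorted(set(pred) - used_p)
    return pairs, unmatched_gold, unmatched_pred


def _check_non_overlapping(anns, name: str) -> None:
    anns = sorted(anns)
    for a, b in zip(anns, anns[1:]):
        if a.overlaps(b):
            raise ContractError(f"{name} annotations overlap: {a} / {b}")


@dataclass
class EvalReport:
    """Soft precision/recall/F plus score-distribution summaries."""

    precision: float
    recall: float
    f_measure: float
    n_gold: int
    n_pred: int
    score_histogram: dict[float, int] = field(default_factory=dict)
    per_class: dict[str, "EvalReport"] = field(default_factory=dict)

    @property
    def soft_mean(self) -> float:
        """Mean soft score over predictions (unmatched predictions score 0)."""
        total = sum(s * c for s, c in self.score_histogram.items())
        n = sum(self.score_histogram.values())
        return total / n if n else 0.0

    @property
    def soft_std(self) -> float:
        mu = self.soft_mean
        n = sum(self.score_histogram.values())
        if not n:
            return 0.0
        var = sum(c * (s - mu) ** 2 for s, c in self.score_histogram.items()) / n
        return var**0.5

    def round_percent(self, value: float) -> float:
        """Percentages are reported to the nearest 0.1%."""
        return round(100 * value, 1)

    def summary(self) -> dict:
        d = {
            "precision_pct": self.round_percent(self.precision),
            "recall_pct": self.round_percent(self.recall),
            "f_measure_pct": self.round_percent(self.f_measure),
            "n_gold": self.n_gold,
            "n_pred": self.n_pred,
        }
        if self.score_histogram:
            d["soft_mean"] = round(self.soft_mean, 3)
            d["soft_std"] = round(self.soft_std, 3)
        for cls, rep in self.per_class.items():
            d[cls] = rep.summary()
        return d


def soft_prf(
    gold: frozenset[EntityAnnotation] | set,
    pred: frozenset[EntityAnnotation] | set,
    per_class: bool = True,
) -> EvalReport:
    """Soft precision/recall/F over one gold/pred annotation pair of sets."""
    pairs, unmatched_gold, unmatched_pred = match_entities(gold, pred)
    scores = [soft_score(g, p) for g, p in pairs]
    total = sum(scores)
    n_gold, n_pred = len(gold), len(pred)
    if n_pred == 0 and n_gold > 0:
        warnings.warn("no predicted entities; precision defined as 0", stacklevel=2)
    if n_gold == 0 and n_pred > 0:
        warnings.warn("no gold entities; recall defined as 0", stacklevel=2)
    precision = total / n_pred if n_pred else 0.0
    recall = total / n_gold if n_gold else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    hist: dict[float, int] = {}
    for s in scores:
        hist[s] = hist.get(s, 0) + 1
    if unmatched_pred:
        hist[0.0] = hist.get(0.0, 0) + len(unmatched_pred)
    report = EvalReport(
        precision=precision,
        recall=recall,
        f_measure=f,
        n_gold=n_gold,
        n_pred=n_pred,
        score_histogram=hist,
    )
    if per_class:
        for cls in EntityClass:
            g_c = {a for a in gold if a.cls is cls}
            p_c = {a for a in pred if a.cls is cls}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report.per_class[cls.value] = soft_prf(g_c, p_c, per_class=False)
    return report


def corpus_soft_prf(
    gold_by_sentence: list[frozenset[EntityAnnotation] | set],
    pred_by_sentence: list[frozenset[EntityAnnotation] | set],
    per_class: bool = True,
) -> EvalReport:
    """Micro-averaged soft P/R/F over aligned per-sentence annotation sets."""
    if len(gold_by_sentence) != len(pred_by_sentence):
        raise ContractError("gold and prediction lists must align")
    total = 0.0
    n_gold = n_pred = 0
    hist: dict[float, int] = {}
    cls_acc: dict[str, list] = {c.value: [0.0, 0, 0] for c in EntityClass}
    for gold, pred in zip(gold_by_sentence, pred_by_sentence):
        pairs, _, unmatched_pred = match_entities(gold, pred)
        for g, p in pairs:
            s = soft_score(g, p)
            total += s
            hist[s] = hist.get(s, 0) + 1
            cls_acc[g.cls.value][0] += s
        if unmatched_pred:
            hist[0.0] = hist.get(0.0, 0) + len(unmatched_pred)
        n_gold += len(gold)
        n_pred += len(pred)
        for c in EntityClass:
            cls_acc[c.value][1] += sum(1 for a in gold if a.cls is c)
            cls_acc[c.value][2] += sum(1 for a in pred if a.cls is c)
    precision = total / n_pred if n_pred else 0.0
    recall = total / n_gold if n_gold else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    report = EvalReport(
        precision=precision,
        recall=recall,
        f_measure=f,
        n_gold=n_gold,
        n_pred=n_pred,
        score_histogram=hist,
    )
    if per_class:
        for c in EntityClass:
            # class-restricted totals reuse the same pairing
            tot, ng, np_ = cls_acc[c.value]
            p = tot / np_ if np_ else 0.0
            r = tot / ng if ng else 0.0
            fc = 2 * p * r / (p + r) if p + r else 0.0
            report.per_class[c.value] = EvalReport(
                precision=p, recall=r, f_measure=fc, n_gold=ng, n_pred=np_
            )
    return report


def filter_confusion(
    gold_labels: list[bool], predicted_labels: list[bool]
) -> dict[str, int]:
    """2x2 confusion counts for the hot-sentence filter (True = medication)."""
    if len(gold_labels) != len(predicted_labels):
        raise ContractError("label lists must have equal length")
    counts = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    for g, p in zip(gold_labels, predicted_labels):
        if g and p:
            counts["tp"] += 1
        elif g and not p:
            counts["fn"] += 1
        elif not g and p:
            counts["fp"] += 1
        else:
            counts["tn"] += 1
    return counts
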