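"""Heuristic BIO repair applied between decoding and entity extraction.

Five rules, applied left to right:

1. ``O`` followed by ``I-X``: the ``I`` becomes ``B-X``.
2. ``B-X`` followed by a different-class ``I-Y``: the ``I`` becomes a ``B``
   of the preceding class (``B-WM I-TCM`` → ``B-WM B-WM``); a config switch
   keeps the I's own class instead.
3. A ``B-X`` directly continuing a same-class ``I-X`` run is merged into it
   (``B-WM I-WM B-WM I-WM`` → ``B-WM I-WM I-WM I-WM``) — in admission notes
   a drug name is rarely followed immediately by another drug.
4. An entity containing ``)`` but no ``(`` is extended leftward so that its
   ``B`` sits on the nearest ``(``; with no ``(`` available it is left alone.
5. An ``O``-labeled ``)`` immediately after an entity end is absorbed into
   the entity; conversely an entity starting with an unmatched ``(`` drops
   that leading parenthesis.

Repairs relabel only — the sequence length never changes — and
``repair_bio`` is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .resources import TagSequence

OPEN_PARENS = "（("
CLOSE_PARENS = "）)"


@dataclass(frozen=True)
class RepairStep:
    rule: int
    position: int
    before: str
    after: str


@dataclass(frozen=True)
class RepairTrace:
    steps: tuple[RepairStep, ...]

    def replay(self, tags: TagSequence) -> TagSequence:
        labels = list(tags.labels)
        for step in self.steps:
            assert labels[step.position] == step.before
            labels[step.position] = step.after
        return TagSequence(tuple(labels))


def repair_bio(
    tags: TagSequence, rule2_keep_class: bool = False, merge_adjacent: bool = True
) -> tuple[TagSequence, RepairTrace]:
    """Apply rules 1-3 left to right; the output is BIO-valid.

    Rules 1 and 2 always run (without them a raw decode may not be a valid
    BIO sequence at all); ``merge_adjacent=False`` disables rule 3.
    """
    labels = list(tags.labels)
    steps: list[RepairStep] = []

    def rewrite(i: int, rule: int, new: str) -> None:
        steps.append(RepairStep(rule=rule, position=i, before=labels[i], after=new))
        labels[i] = new

    for i, lab in enumerate(labels):
        prev = labels[i - 1] if i > 0 else "O"
        if lab.startswith("I-"):
            cls = lab[2:]
            if prev == "O":
                rewrite(i, 1, f"B-{cls}")
            elif prev[2:] != cls:
                new_cls = cls if rule2_keep_class else prev[2:]
                rewrite(i, 2, f"B-{new_cls}")
                # the rewritten B may itself continue a same-class run
                if merge_adjacent and prev == f"I-{new_cls}":
                    rewrite(i, 3, f"I-{new_cls}")
        elif lab.startswith("B-") and merge_adjacent:
            cls = lab[2:]
            if prev == f"I-{cls}":
                rewrite(i, 3, f"I-{cls}")

    return TagSequence(tuple(labels)), RepairTrace(tuple(steps))


def balance_parentheses(tags: TagSequence, chars: str) -> TagSequence:
    """Apply the parenthesis rules 4 and 5 (full-width and ASCII alike)."""
    labels = list(tags.labels)
    n = len(labels)
    assert len(chars) == n, "tags and characters must align"

    for start, end, cls in _entities(labels):
        span = chars[start:end]
        has_open = any(c in OPEN_PARENS for c in span)
        has_close = any(c in CLOSE_PARENS for c in span)
        if has_close and not has_open:
            # rule 4: move B leftward onto the nearest "("
            pos = None
            for j in range(start - 1, -1, -1):
                if chars[j] in OPEN_PARENS:
                    pos = j
                    break
            if pos is not None:
                labels[pos] = f"B-{cls}"
                for j in range(pos + 1, end):
                    labels[j] = f"I-{cls}"
        elif end < n and chars[end] in CLOSE_PARENS and labels[end] == "O":
            # rule 5: absorb a trailing O-labeled ")"
            labels[end] = f"I-{cls}"
        elif chars[start] in OPEN_PARENS and not has_close and (
            end >= n or chars[end] not in CLOSE_PARENS
        ):
            # rule 5, final clause: strip an unmatched leading "("
            labels[start] = "O"
            if end - start > 1:
                labels[start + 1] = f"B-{cls}"

    return TagSequence(tuple(labels))


def _entities(labels: list[str]):
    out = []
    start = None
    cls = None
    for i, lab in enumerate(labels + ["O"]):
        if lab.startswith("B-"):
            if start is not None:
                out.append((start, i, cls))
            start, cls = i, lab[2:]
        elif lab == "O" or (start is not None and lab[2:] != cls):
            if start is not None:
                out.append((start, i, cls))
                start, cls = None, None
    return out
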