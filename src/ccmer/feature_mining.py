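"""Statistical keyword mining for the sentence filter (SF4/SF5).

2- to 4-character keywords are mined separately from the positive sentence
set (sentences that mention a drug) and the negative set.  Candidates start
as character bigrams; a bigram is extended with the following overlapping
bigram into 3- and 4-grams whenever the extended string itself is frequent.
The retained top fraction is weighted by relative frequency, e.g. a keyword
occurring 114 times among 2524 total retained-keyword occurrences gets
weight 114/2524 ≈ 0.045.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .resources import ContractError


@dataclass(frozen=True)
class WeightedKeywordList:
    """Retained keywords with occurrence counts and normalized weights."""

    entries: tuple[tuple[str, int, float], ...]  # (keyword, count, weight)
    polarity: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.entries:
            total = sum(w for _, _, w in self.entries)
            if abs(total - 1.0) > 1e-9:
                raise ContractError(f"weights sum to {total}, expected 1")
        for kw, count, _ in self.entries:
            if not 2 <= len(kw) <= 4:
                raise ContractError(f"keyword length out of range: {kw!r}")
            if count < 1:
                raise ContractError(f"non-positive count for {kw!r}")

    def weights(self) -> dict[str, float]:
        return {kw: w for kw, _, w in self.entries}

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"# polarity: {self.polarity}\n")
            for kw, count, weight in self.entries:
                fh.write(f"{kw}\t{count}\t{weight!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "WeightedKeywordList":
        polarity = "positive"
        entries = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if line.startswith("# polarity:"):
                polarity = line.split(":", 1)[1].strip()
                continue
            if not line.strip() or line.startswith("#"):
                continue
            kw, count, weight = line.split("\t")
            entries.append((kw, int(count), float(weight)))
        return cls(entries=tuple(entries), polarity=polarity)


def count_occurrences(needle: str, haystack: str) -> int:
    """All (possibly overlapping) occurrences of needle in haystack."""
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def mine_keywords(
    sentences: Sequence[str],
    retain_fraction: float = 0.3,
    min_count: int = 2,
) -> list[tuple[str, int]]:
    """Mine ranked 2-4-character keywords from a sentence set.

    Bigrams are counted first; a candidate n-gram (n = 2, 3) is extended by
    the overlapping following bigram when the (n+1)-gram's own corpus count
    reaches ``min_count``.  Candidates are ranked by count descending with a
    lexicographic tiebreak, and the top ``ceil(retain_fraction * n)`` are
    returned.
    """
    if not sentences:
        raise ContractError("mine_keywords requires a non-empty sentence set")
    if not 0 < retain_fraction <= 1:
        raise ContractError("retain_fraction must lie in (0, 1]")

    # Counting every 2/3/4-gram directly is equivalent to extending frequent
    # bigrams with their overlapping successors: an (n+1)-gram can only reach
    # min_count if its n-gram prefix does (occurrence counts are monotone
    # under prefix), so the extension frontier enumerates exactly the n-grams
    # kept here.  Overlapping occurrences all count.
    grams: Counter[str] = Counter()
    for s in sentences:
        for n in (2, 3, 4):
            for i in range(len(s) - n + 1):
                g = s[i : i + n]
                if not any(c.isspace() for c in g):  # no keywords across whitespace
                    grams[g] += 1
    candidates = {g: c for g, c in grams.items() if c >= min_count}

    ranked = sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))
    keep = math.ceil(retain_fraction * len(ranked))
    return ranked[:keep]


def compute_weights(
    keyword_counts: Iterable[tuple[str, int]], polarity: str = "positive"
) -> WeightedKeywordList:
    """Weight retained keywords by their share of total occurrences."""
    counts = list(keyword_counts)
    if not counts:
        raise ContractError("compute_weights requires a non-empty retained list")
    total = sum(c for _, c in counts)
    if total <= 0:
        raise ContractError("total keyword count must be positive")
    entries = tuple((kw, c, c / total) for kw, c in counts)
    return WeightedKeywordList(entries=entries, polarity=polarity)
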