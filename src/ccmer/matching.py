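"""Greedy dictionary matching shared by the filter and the tagger."""

from __future__ import annotations

from typing import Sequence


def forward_max_match(
    text: Sequence[str],
    term_set,
    max_len: int | None = None,
) -> list[tuple[int, int]]:
    """Forward maximum matching: left-to-right, longest term at each position.

    Works on character strings (terms are strings) or on syllable sequences
    (terms are tuples of syllables).  At each position the longest dictionary
    term starting there is emitted and the scan continues after it; if no
    term starts there, the scan advances one unit.  Output spans never
    overlap.
    """
    if not term_set:
        return []
    if max_len is None:
        max_len = max(len(t) for t in term_set)
    n = len(text)
    spans: list[tuple[int, int]] = []
    i = 0
    is_str = isinstance(text, str)
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            piece = text[i : i + length] if is_str else tuple(text[i : i + length])
            if piece in term_set:
                spans.append((i, i + length))
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return spans


def term_start_positions(text: str, terms) -> list[int]:
    """Start offsets of every (possibly overlapping) term occurrence."""
    starts = []
    for term in terms:
        pos = text.find(term)
        while pos >= 0:
            starts.append(pos)
            pos = text.find(term, pos + 1)
    return sorted(set(starts))
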