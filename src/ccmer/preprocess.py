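"""Text normalization, sentence splitting, pinyin transliteration, sections.

Raw admission-note text is normalized with a strictly length-preserving
character map (digits -> ``9``, Greek letters -> ``@``) so that dose figures
collapse onto a single pattern while character offsets stay valid.  Stopwords
are deliberately never removed: Chinese transliterations of Western drug
names are full of function characters, and deleting them would destroy
entity spans.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field

from .resources import LexiconSet, SentenceRecord

logger = logging.getLogger(__name__)

#: Placeholder syllable for Chinese characters absent from the pinyin map.
UNKNOWN_SYLLABLE = "▯"  # ▯

#: Sentence terminators; each ends the span that contains it.
TERMINATORS = "。；！？\n"  # 。；！？ and newline
CLAUSE_TERMINATORS = "，,"  # ，and ASCII comma

NONE_SECTION = None


def normalize_text(text: str) -> str:
    """Map every decimal digit to ``9`` and every Greek letter to ``@``.

    The mapping is 1:1, so ``len(normalize_text(t)) == len(t)`` and character
    offsets computed before/after normalization agree.  Idempotent.
    """
    out = []
    for ch in text:
        if ch.isdigit() and unicodedata.category(ch) == "Nd":
            out.append("9")
        elif _is_greek(ch):
            out.append("@")
        else:
            out.append(ch)
    return "".join(out)


def _is_greek(ch: str) -> bool:
    o = ord(ch)
    return 0x0370 <= o <= 0x03FF or o == 0x00B5  # Greek block + micro sign


def split_sentences(text: str, split_clauses: bool = False) -> list[tuple[int, int]]:
    """Split normalized text into (start, end) sentence spans.

    A terminator (。；！？ or newline; plus commas when ``split_clauses``)
    ends a span and is included in it.  Whitespace between sentences belongs
    to no span; the spans partition the non-whitespace text.
    """
    terms = TERMINATORS + (CLAUSE_TERMINATORS if split_clauses else "")
    spans: list[tuple[int, int]] = []
    start: int | None = None
    for i, ch in enumerate(text):
        if start is None:
            if ch.isspace():
                continue
            start = i
        if ch in terms:
            spans.append((start, i + 1))
            start = None
    if start is not None:
        spans.append((start, len(text)))
    return spans


def transliterate(chars: str, pinyin_map) -> tuple[str, ...]:
    """Map characters to toneless lowercase pinyin, 1:1 aligned.

    Non-Chinese characters map to themselves.  A Chinese character missing
    from the map yields the sentinel ``▯`` and is logged once per character.
    """
    out = []
    for ch in chars:
        syll = pinyin_map.get(ch)
        if syll is not None:
            out.append(syll)
        elif _is_cjk(ch):
            if ch not in _warned_chars:
                _warned_chars.add(ch)
                logger.warning("character %r missing from pinyin map", ch)
            out.append(UNKNOWN_SYLLABLE)
        else:
            out.append(ch)
    return tuple(out)


_warned_chars: set[str] = set()


def _is_cjk(ch: str) -> bool:
    o = ord(ch)
    return 0x3400 <= o <= 0x9FFF or 0xF900 <= o <= 0xFAFF


def detect_sections(
    raw_text: str, section_headers: tuple[str, ...]
) -> list[tuple[str | None, tuple[int, int]]]:
    """Find section spans from line-initial header matches.

    A section starts at each line-initial occurrence of a header (the longest
    matching header wins) and extends to the next header or end of text.
    Text before the first header belongs to the NONE section.
    """
    if not raw_text:
        return []
    starts: list[tuple[int, str]] = []
    line_start = 0
    headers = sorted(section_headers, key=len, reverse=True)
    n = len(raw_text)
    i = 0
    while i <= n:
        if i == n or raw_text[i] == "\n":
            line = raw_text[line_start:i]
            for h in headers:
                if line.startswith(h):
                    starts.append((line_start, h))
                    break
            line_start = i + 1
        i += 1
    sections: list[tuple[str | None, tuple[int, int]]] = []
    if not starts or starts[0][0] > 0:
        end = starts[0][0] if starts else n
        sections.append((NONE_SECTION, (0, end)))
    for (pos, header), nxt in zip(starts, starts[1:] + [(n, "")]):
        sections.append((header, (pos, nxt[0])))
    return sections


@dataclass
class NoteDocument:
    """A preprocessed admission note: sections and sentence records."""

    note_id: str
    raw_text: str
    sections: list[tuple[str | None, tuple[int, int]]] = field(default_factory=list)
    sentences: list[SentenceRecord] = field(default_factory=list)
    #: spans of ``sentences`` in the normalized note text, aligned 1:1
    sentence_spans: list[tuple[int, int]] = field(default_factory=list)


def preprocess_note(
    note_id: str,
    raw_text: str,
    lexicons: LexiconSet,
    split_clauses: bool = False,
) -> NoteDocument:
    """Normalize, section, split and transliterate one raw note."""
    norm = normalize_text(raw_text)
    sections = detect_sections(norm, lexicons.section_headers)
    spans = split_sentences(norm, split_clauses=split_clauses)
    sentences = []
    for start, end in spans:
        text = norm[start:end]
        section = _section_of(start, sections)
        sentences.append(
            SentenceRecord(
                chars=text,
                pinyin=transliterate(text, lexicons.pinyin_map),
                section=section,
                note_id=note_id,
            )
        )
    return NoteDocument(
        note_id=note_id,
        raw_text=raw_text,
        sections=sections,
        sentences=sentences,
        sentence_spans=spans,
    )


def _section_of(pos: int, sections) -> str | None:
    for header, (s, e) in sections:
        if s <= pos < e:
            return header
    return sections[-1][0] if sections else NONE_SECTION
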