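"""Core domain types and readers/writers for lexicons and annotated corpora.

The package recognizes two classes of medication entities in Chinese
admission notes: Western-medicine (WM) drug names and traditional-Chinese-
medicine (TCM) drug names.  Annotated corpora are exchanged as two-column
CoNLL-style files (character TAB label, blank line between sentences) over
the five-label character tagset {B-WM, I-WM, B-TCM, I-TCM, O}; lexicons are
plain UTF-8 text, one term per line, ``#`` comment lines ignored.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class EntityClass(enum.Enum):
    """The two medication entity classes."""

    WM = "WM"
    TCM = "TCM"

    def __str__(self) -> str:  # serialized form
        return self.value


#: The five character labels of the BIO2 scheme with class subscripts.
LABELS = ("O", "B-WM", "I-WM", "B-TCM", "I-TCM")


class ContractError(ValueError):
    """An operation was called with input violating its preconditions."""


class ResourceError(OSError):
    """A required file is missing or unreadable."""


class ParseError(ValueError):
    """A data file does not conform to its format."""


@dataclass(frozen=True, order=True)
class EntityAnnotation:
    """A classed character span, 0-based half-open, on normalized text."""

    start: int
    end: int
    cls: EntityClass
    surface: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ContractError(
                f"invalid span ({self.start}, {self.end}): need 0 <= start < end"
            )
        if self.surface and len(self.surface) != self.end - self.start:
            raise ContractError("surface length must equal end - start")

    def overlaps(self, other: "EntityAnnotation") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class SentenceRecord:
    """A sentence as the tagger sees it: characters, aligned pinyin, section."""

    chars: str
    pinyin: Sequence[str]
    section: str | None = None
    note_id: str = ""
    gold: frozenset[EntityAnnotation] = frozenset()

    def __post_init__(self) -> None:
        if len(self.pinyin) != len(self.chars):
            raise ContractError(
                f"pinyin length {len(self.pinyin)} != chars length {len(self.chars)}"
            )
        golds = sorted(self.gold)
        for g in golds:
            if g.end > len(self.chars):
                raise ContractError(f"gold span {g} exceeds sentence length")
        for a, b in zip(golds, golds[1:]):
            if a.overlaps(b):
                raise ContractError(f"overlapping gold spans {a} and {b}")


@dataclass(frozen=True)
class TagSequence:
    """Per-character labels over the five-label set."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [l for l in self.labels if l not in LABELS]
        if bad:
            raise ContractError(f"unknown labels: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def is_bio_valid(self) -> bool:
        prev = "O"
        for lab in self.labels:
            if lab.startswith("I-"):
                cls = lab[2:]
                if prev == "O" or prev[2:] != cls:
                    return False
            prev = lab
        return True


@dataclass
class LexiconSet:
    """All term lists, pattern lexicons, and the character->pinyin map."""

    wm_terms: frozenset[str] = frozenset()
    tcm_terms: frozenset[str] = frozenset()
    symbol_list: frozenset[str] = frozenset()
    dose_units_wm: frozenset[str] = frozenset()
    dose_units_tcm: frozenset[str] = frozenset()
    routes_wm: frozenset[str] = frozenset()
    routes_tcm: frozenset[str] = frozenset()
    forms_wm: frozenset[str] = frozenset()
    forms_tcm: frozenset[str] = frozenset()
    freqs_wm: frozenset[str] = frozenset()
    freqs_tcm: frozenset[str] = frozenset()
    section_headers: tuple[str, ...] = ()
    pinyin_map: Mapping[str, str] = field(default_factory=dict)

    def all_drug_terms(self) -> frozenset[str]:
        return self.wm_terms | self.tcm_terms

    def replace(self, **kwargs) -> "LexiconSet":
        from dataclasses import replace

        return replace(self, **kwargs)


LEXICON_KINDS = (
    "wm_dict",
    "tcm_dict",
    "symbols",
    "dose_units_wm",
    "dose_units_tcm",
    "routes_wm",
    "routes_tcm",
    "forms_wm",
    "forms_tcm",
    "freqs_wm",
    "freqs_tcm",
    "section_headers",
)


def load_lexicon(path: str | Path, kind: str = "terms") -> frozenset[str]:
    """Load a one-term-per-line lexicon file.

    Terms are whitespace-trimmed and deduplicated; case of Latin terms is
    preserved.  Lines starting with ``#`` are comments.  An empty file yields
    an empty set with a warning.
    """
    path = Path(path)
    if not path.is_file():
        raise ResourceError(f"lexicon file not found: {path}")
    terms = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        term = line.strip()
        if term and not term.startswith("#"):
            terms.add(term)
    if not terms:
        warnings.warn(f"lexicon file {path} ({kind}) is empty", stacklevel=2)
    return frozenset(terms)


def load_pinyin_map(path: str | Path) -> dict[str, str]:
    """Load a two-column (character TAB syllable) pinyin map."""
    path = Path(path)
    if not path.is_file():
        raise ResourceError(f"pinyin map not found: {path}")
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
        char, syll = parts[0].strip(), parts[1].strip()
        if len(char) != 1:
            raise ParseError(f"{path}:{lineno}: key must be a single character")
        mapping[char] = syll.lower()
    return mapping


def _data_path(name: str):
    return _importlib_resources.files("ccmer.data").joinpath(name)


def default_lexicons() -> LexiconSet:
    """The small built-in lexicon set used by tests, demos and the generator.

    Users working on real notes should supply their own dictionaries; these
    defaults contain only a few dozen drug names each.
    """
    import contextlib

    with contextlib.ExitStack() as stack:
        paths = {
            name: stack.enter_context(_importlib_resources.as_file(_data_path(fn)))
            for name, fn in [
                ("wm", "wm_dict.txt"),
                ("tcm", "tcm_dict.txt"),
                ("sym", "symbols.txt"),
                ("du_wm", "dose_units_wm.txt"),
                ("du_tcm", "dose_units_tcm.txt"),
                ("rt_wm", "routes_wm.txt"),
                ("rt_tcm", "routes_tcm.txt"),
                ("fm_wm", "forms_wm.txt"),
                ("fm_tcm", "forms_tcm.txt"),
                ("fq_wm", "freqs_wm.txt"),
                ("fq_tcm", "freqs_tcm.txt"),
                ("sec", "section_headers.txt"),
                ("py", "pinyin_map.tsv"),
            ]
        }
        headers = tuple(
            t
            for t in Path(paths["sec"]).read_text(encoding="utf-8").splitlines()
            if t.strip() and not t.startswith("#")
        )
        return LexiconSet(
            wm_terms=load_lexicon(paths["wm"], "wm_dict"),
            tcm_terms=load_lexicon(paths["tcm"], "tcm_dict"),
            symbol_list=load_lexicon(paths["sym"], "symbols"),
            dose_units_wm=load_lexicon(paths["du_wm"], "dose_units_wm"),
            dose_units_tcm=load_lexicon(paths["du_tcm"], "dose_units_tcm"),
            routes_wm=load_lexicon(paths["rt_wm"], "routes_wm"),
            routes_tcm=load_lexicon(paths["rt_tcm"], "routes_tcm"),
            forms_wm=load_lexicon(paths["fm_wm"], "forms_wm"),
            forms_tcm=load_lexicon(paths["fm_tcm"], "forms_tcm"),
            freqs_wm=load_lexicon(paths["fq_wm"], "freqs_wm"),
            freqs_tcm=load_lexicon(paths["fq_tcm"], "freqs_tcm"),
            section_headers=headers,
            pinyin_map=load_pinyin_map(paths["py"]),
        )


# ---------------------------------------------------------------------------
# BIO file serialization
# ---------------------------------------------------------------------------

#: whitespace characters are escaped in the first column so that the
#: two-column format stays line-oriented
_WHITESPACE_ESCAPES = {"\n": "\\n", "\t": "\\t", " ": "\\s", "　": "\\S"}
_WHITESPACE_UNESCAPES = {v: k for k, v in _WHITESPACE_ESCAPES.items()}


def read_bio_file(path: str | Path) -> list[tuple[SentenceRecord, TagSequence]]:
    """Read a two-column (character TAB label) sequence file.

    Sentences are separated by blank lines.  The returned SentenceRecords
    carry identity pinyin (the file format does not store pinyin); callers
    needing aligned pinyin should re-transliterate.
    """
    path = Path(path)
    if not path.is_file():
        raise ResourceError(f"BIO file not found: {path}")
    out: list[tuple[SentenceRecord, TagSequence]] = []
    chars: list[str] = []
    labels: list[str] = []

    def flush() -> None:
        if chars:
            text = "".join(chars)
            rec = SentenceRecord(chars=text, pinyin=tuple(text))
            out.append((rec, TagSequence(tuple(labels))))
            chars.clear()
            labels.clear()

    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            flush()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'char<TAB>label'")
        char, label = parts
        char = _WHITESPACE_UNESCAPES.get(char, char)
        if len(char) != 1:
            raise ParseError(f"{path}:{lineno}: first column must be one character")
        if label not in LABELS:
            raise ParseError(f"{path}:{lineno}: unknown label {label!r}")
        chars.append(char)
        labels.append(label)
    flush()
    return out


def write_bio_file(
    records: Iterable[tuple[SentenceRecord, TagSequence]], path: str | Path
) -> None:
    """Write sentence/tag pairs in the two-column format (round-trips)."""
    path = Path(path)
    try:
        with path.open("w", encoding="utf-8") as fh:
            first = True
            for rec, tags in records:
                if len(tags) != len(rec.chars):
                    raise ContractError("tag length does not match sentence length")
                if not first:
                    fh.write("\n")
                first = False
                for char, label in zip(rec.chars, tags):
                    fh.write(f"{_WHITESPACE_ESCAPES.get(char, char)}\t{label}\n")
    except OSError as exc:
        raise ResourceError(f"cannot write BIO file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Entity <-> tag conversion
# ---------------------------------------------------------------------------

def encode_tags(sentence: SentenceRecord) -> TagSequence:
    """Encode a sentence's (non-overlapping) gold annotations as BIO labels."""
    labels = ["O"] * len(sentence.chars)
    for ann in sorted(sentence.gold):
        labels[ann.start] = f"B-{ann.cls.value}"
        for i in range(ann.start + 1, ann.end):
            labels[i] = f"I-{ann.cls.value}"
    return TagSequence(tuple(labels))


def decode_entities(
    tags: TagSequence, sentence: SentenceRecord
) -> frozenset[EntityAnnotation]:
    """Decode a BIO-valid tag sequence into entity annotations.

    One annotation is produced per maximal B followed by same-class I run.
    """
    if len(tags) != len(sentence.chars):
        raise ContractError("tag length does not match sentence length")
    if not tags.is_bio_valid():
        raise ContractError("decode_entities requires a BIO-valid sequence")
    out = []
    start = None
    cls = None
    for i, lab in enumerate(tags):
        if lab.startswith("B-"):
            if start is not None:
                out.append(_make_ann(start, i, cls, sentence))
            start, cls = i, lab[2:]
        elif lab == "O":
            if start is not None:
                out.append(_make_ann(start, i, cls, sentence))
            start, cls = None, None
        # I- continues the open run (validity guaranteed above)
    if start is not None:
        out.append(_make_ann(start, len(tags), cls, sentence))
    return frozenset(out)


def _make_ann(start: int, end: int, cls: str, sentence: SentenceRecord) -> EntityAnnotation:
    return EntityAnnotation(
        start=start, end=end, cls=EntityClass(cls), surface=sentence.chars[start:end]
    )
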