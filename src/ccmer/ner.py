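"""Character-level medication entity tagger and dictionary baseline.

Feature families per character ``i`` (window = context window size, CWS):

* F1 — 1/2/3-grams of characters and, optionally, of aligned pinyin within
  the window (CWS ∈ {1,2,3}; windows larger than 3 add noise in short
  clinical clauses, so CWS is capped at 3).
* F2 — dictionary membership: is the character covered by a forward-
  maximum-match span of the TCM/WM dictionary, on characters and on pinyin.
* F3 — 16 indicators crossing {dose unit, route, form, frequency} ×
  {TCM, WM} × {starts at i..i+3, starts at i−3..i−1}.
* F4 — pattern flags over the window: contains the digit ``9``, the Greek
  placeholder ``@``, English letters, or a time expression.
* F5 — admission-note structure: is the owning section header in the
  configured list, plus the section label itself.
* F6 — label history.  In a first-order CRF the category of preceding
  characters is carried by the label-bigram transition weights (the
  default); an optional greedy mode injects the previous three predicted
  labels as observation features instead.

The default feature set is F1+F3+F4+F5+F6 at CWS = 3 with both character
and pinyin n-grams, the configuration that performs best in ablations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

from . import crf as _crf
from .matching import forward_max_match, term_start_positions
from .preprocess import normalize_text, transliterate
from .resources import (
    LABELS,
    ContractError,
    EntityAnnotation,
    EntityClass,
    LexiconSet,
    SentenceRecord,
    TagSequence,
)

__all__ = [
    "FeatureConfig",
    "NERModel",
    "extract_char_features",
    "forward_max_match",
    "train_crf",
    "tag",
    "baseline_dict_recognize",
]

BOS = "<S>"
EOS = "</S>"

_TIME_RE = re.compile(r"9\s*(?:[时日周年月天分秒]|[hd]\b|[hd]$)")

ALL_GROUPS = frozenset({"F1", "F2", "F3", "F4", "F5", "F6"})
DEFAULT_GROUPS = frozenset({"F1", "F3", "F4", "F5", "F6"})


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families the tagger uses and at what window size."""

    cws: int = 3
    enabled_groups: frozenset[str] = DEFAULT_GROUPS
    f1_variant: str = "chars+pinyin"  # or "chars"
    f6_observed: bool = False  # greedy label-history mode

    def __post_init__(self) -> None:
        if self.cws not in (1, 2, 3):
            raise ContractError("cws must be 1, 2 or 3 (windows >= 4 are too noisy)")
        unknown = self.enabled_groups - ALL_GROUPS
        if unknown:
            raise ContractError(f"unknown feature groups: {sorted(unknown)}")
        if self.f1_variant not in ("chars", "chars+pinyin"):
            raise ContractError("f1_variant must be 'chars' or 'chars+pinyin'")

    def to_dict(self) -> dict:
        return {
            "cws": self.cws,
            "enabled_groups": sorted(self.enabled_groups),
            "f1_variant": self.f1_variant,
            "f6_observed": self.f6_observed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            cws=d["cws"],
            enabled_groups=frozenset(d["enabled_groups"]),
            f1_variant=d["f1_variant"],
            f6_observed=d.get("f6_observed", False),
        )


def _padded(seq: Sequence[str], i: int) -> str:
    if i < 0:
        return BOS
    if i >= len(seq):
        return EOS
    return seq[i]


def _ngram_feats(seq: Sequence[str], i: int, cws: int, prefix: str) -> list[str]:
    feats = []
    for off in range(-cws, cws + 1):
        feats.append(f"{prefix}1[{off}]={_padded(seq, i + off)}")
    for j in range(-cws, cws):
        feats.append(
            f"{prefix}2[{j}]={_padded(seq, i + j)}|{_padded(seq, i + j + 1)}"
        )
    for j in range(-cws, cws - 1):
        feats.append(
            f"{prefix}3[{j}]="
            f"{_padded(seq, i + j)}|{_padded(seq, i + j + 1)}|{_padded(seq, i + j + 2)}"
        )
    return feats


_F3_CATEGORIES = (
    ("Dose", "dose_units_tcm", "dose_units_wm"),
    ("Route", "routes_tcm", "routes_wm"),
    ("Form", "forms_tcm", "forms_wm"),
    ("Freq", "freqs_tcm", "freqs_wm"),
)


def extract_char_features(
    sentence: SentenceRecord,
    lexicons: LexiconSet,
    config: FeatureConfig = FeatureConfig(),
    gold_tags: Sequence[str] | None = None,
) -> list[list[str]]:
    """Emit the per-character feature strings for one sentence.

    Pure: identical (sentence, lexicons, config) give identical output.
    ``gold_tags`` is only consulted in the greedy label-history mode, where
    training injects the gold previous labels.
    """
    chars = sentence.chars
    pinyin = tuple(sentence.pinyin)
    n = len(chars)
    groups = config.enabled_groups
    feats: list[list[str]] = [[] for _ in range(n)]

    if "F1" in groups:
        for i in range(n):
            feats[i] += _ngram_feats(chars, i, config.cws, "C")
            if config.f1_variant == "chars+pinyin":
                feats[i] += _ngram_feats(pinyin, i, config.cws, "P")

    if "F2" in groups:
        if not lexicons.wm_terms or not lexicons.tcm_terms:
            raise ContractError("F2 requires both drug dictionaries")
        pmap = lexicons.pinyin_map
        for name, terms in (("TCM", lexicons.tcm_terms), ("WM", lexicons.wm_terms)):
            nterms = frozenset(normalize_text(t) for t in terms)
            cov = _coverage(forward_max_match(chars, nterms), n)
            pterms = {transliterate(t, pmap) for t in nterms}
            pcov = _coverage(forward_max_match(pinyin, pterms), n)
            for i in range(n):
                if cov[i]:
                    feats[i].append(f"F2-InDict{name}")
                if pcov[i]:
                    feats[i].append(f"F2-InDict{name}Pinyin")

    if "F3" in groups:
        for cat, tcm_attr, wm_attr in _F3_CATEGORIES:
            for side, attr in (("TCM", tcm_attr), ("WM", wm_attr)):
                terms = getattr(lexicons, attr)
                if not terms:
                    raise ContractError(f"F3 requires non-empty {attr}")
                starts = set(term_start_positions(chars, {normalize_text(t) for t in terms}))
                for i in range(n):
                    if any(s in starts for s in range(i, min(i + 4, n))):
                        feats[i].append(f"F3-Cur{side}{cat}")
                    if any(s in starts for s in range(max(i - 3, 0), i)):
                        feats[i].append(f"F3-Pre{side}{cat}")

    if "F4" in groups:
        w = config.cws
        for i in range(n):
            window = chars[max(i - w, 0) : i + w + 1]
            if "9" in window:
                feats[i].append("F4-HasNum9")
            if "@" in window:
                feats[i].append("F4-HasToken@")
            if any(c.isascii() and c.isalpha() for c in window):
                feats[i].append("F4-HasEnglish")
            if _TIME_RE.search(window):
                feats[i].append("F4-HasTime")

    if "F5" in groups:
        section = sentence.section
        in_list = section is not None and section in lexicons.section_headers
        for i in range(n):
            if in_list:
                feats[i].append("F5-InListSectionName")
            feats[i].append(f"F5-Section={section or 'NONE'}")

    if "F6" in groups and config.f6_observed:
        if gold_tags is None:
            raise ContractError(
                "greedy F6 features need gold_tags at training time; "
                "use tag() for inference"
            )
        for i in range(n):
            for back in (1, 2, 3):
                lab = gold_tags[i - back] if i - back >= 0 else BOS
                feats[i].append(f"F6[-{back}]={lab}")
    # default F6 realization: label-bigram transitions inside the CRF

    return feats


def _coverage(spans: list[tuple[int, int]], n: int) -> list[bool]:
    cov = [False] * n
    for s, e in spans:
        for i in range(s, e):
            cov[i] = True
    return cov


@dataclass
class NERModel:
    """A trained CRF plus the feature configuration it was trained with."""

    crf: _crf.LinearChainCRF
    config: FeatureConfig
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        self.crf.meta = dict(self.crf.meta, feature_config=self.config.to_dict())
        self.crf.save(path)

    @classmethod
    def load(cls, path) -> "NERModel":
        model = _crf.LinearChainCRF.load(path)
        cfg = FeatureConfig.from_dict(model.meta["feature_config"])
        return cls(crf=model, config=cfg, meta=model.meta)


def train_crf(
    sentences: Sequence[SentenceRecord],
    tag_sequences: Sequence[TagSequence],
    lexicons: LexiconSet,
    config: FeatureConfig = FeatureConfig(),
    c2: float = 0.1,
    maxiter: int = 80,
    seed: int = 0,
) -> NERModel:
    """Train the character tagger (quasi-Newton optimization, deterministic).

    ``seed`` is accepted for interface symmetry; the objective and optimizer
    contain no randomness, so identical data and settings always reproduce
    identical weights.
    """
    if not sentences:
        raise ContractError("training set must be non-empty")
    featurized = [
        extract_char_features(
            s, lexicons, config, gold_tags=tuple(t) if config.f6_observed else None
        )
        for s, t in zip(sentences, tag_sequences)
    ]
    model = _crf.train(
        featurized,
        [tuple(t) for t in tag_sequences],
        labels=LABELS,
        c2=c2,
        maxiter=maxiter,
        meta={"seed": seed},
    )
    return NERModel(crf=model, config=config, meta=dict(model.meta))


def tag(
    model: NERModel,
    sentence: SentenceRecord,
    lexicons: LexiconSet,
    config: FeatureConfig | None = None,
) -> TagSequence:
    """Viterbi-decode a label per character (length-preserving)."""
    if config is not None and config != model.config:
        raise ContractError("feature config differs from the one used in training")
    cfg = model.config
    if not sentence.chars:
        return TagSequence(())
    if cfg.f6_observed:
        base = extract_char_features(
            sentence, lexicons, replace(cfg, f6_observed=False)
        )

        def step(t, prev):
            if t >= len(sentence.chars):
                return None
            fs = list(base[t])
            for back in (1, 2, 3):
                lab = prev[t - back] if t - back >= 0 else BOS
                fs.append(f"F6[-{back}]={lab}")
            return fs

        return TagSequence(model.crf.decode_greedy(step))
    feats = extract_char_features(sentence, lexicons, cfg)
    return TagSequence(model.crf.decode(feats))


def baseline_dict_recognize(
    sentence: SentenceRecord, lexicons: LexiconSet, use_pinyin: bool = True
) -> frozenset[EntityAnnotation]:
    """Dictionary-only recognizer: forward maximum matching on characters
    and on pinyin, the pinyin channel recovering homophone misspellings.

    Character matches win conflicts with pinyin matches; remaining overlaps
    are resolved longest-first.  Class comes from the source dictionary
    (WM preferred when a term or its pinyin occurs in both).
    ``use_pinyin=False`` disables the pinyin channel (characters only).
    """
    chars = sentence.chars
    pinyin = tuple(sentence.pinyin)
    pmap = lexicons.pinyin_map
    wm = frozenset(normalize_text(t) for t in lexicons.wm_terms)
    tcm = frozenset(normalize_text(t) for t in lexicons.tcm_terms)

    char_spans = [
        (s, e, EntityClass.WM if chars[s:e] in wm else EntityClass.TCM)
        for s, e in forward_max_match(chars, wm | tcm)
    ]

    py_spans: list[tuple[int, int, EntityClass]] = []
    if use_pinyin:
        wm_py = {transliterate(t, pmap) for t in wm}
        tcm_py = {transliterate(t, pmap) for t in tcm}
        py_spans = [
            (s, e, EntityClass.WM if tuple(pinyin[s:e]) in wm_py else EntityClass.TCM)
            for s, e in forward_max_match(pinyin, wm_py | tcm_py)
        ]

    chosen: list[tuple[int, int, EntityClass]] = list(char_spans)
    candidates = sorted(py_spans, key=lambda t: (-(t[1] - t[0]), t[0]))
    for s, e, cls in candidates:
        if all(not (s < ce and cs < e) for cs, ce, _ in chosen):
            chosen.append((s, e, cls))
    return frozenset(
        EntityAnnotation(start=s, end=e, cls=cls, surface=chars[s:e])
        for s, e, cls in chosen
    )
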