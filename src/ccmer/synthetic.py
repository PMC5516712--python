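"""Synthetic annotated admission-note corpora.

The generator emulates the statistical structure the cascade assumes —
sectioned notes in which only a few percent of sentences mention drugs
(default rate 0.04), a roughly 73/27 WM/TCM entity mix, medication
sentences built from route/dose/frequency collocation templates, lab-result
sentences containing drug-like terms (血药浓度 lines such as 地高辛0.7ng/ml
that are *not* medication events), optional homophone typos in drug names,
and a held-out fraction of drug names that never occurs in the training
split nor in the emitted dictionaries.

It is NOT a clinically realistic note simulator: sentence templates are
few, section length distributions are arbitrary, and no negation/coreference
phenomena are modeled.  What it supports is controlled end-to-end testing
of the filter, the tagger, the repair rules and the scorer.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace as _dc_replace

from .preprocess import NoteDocument, normalize_text, preprocess_note, transliterate
from .resources import (
    ContractError,
    EntityAnnotation,
    EntityClass,
    LexiconSet,
    SentenceRecord,
    default_lexicons,
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_notes: int = 100
    med_sentence_rate: float = 0.04
    wm_fraction: float = 0.732
    typo_rate: float = 0.0
    lab_confusable_rate: float = 0.3
    alias_rate: float = 0.1
    held_out_fraction: float = 0.0
    train_fraction: float = 2 / 3
    n_wm_names: int | None = None  # cap on dictionary size, None = all
    n_tcm_names: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.med_sentence_rate,
            self.wm_fraction,
            self.typo_rate,
            self.lab_confusable_rate,
            self.alias_rate,
            self.held_out_fraction,
            self.train_fraction,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ContractError("all rates must lie in [0, 1]")
        if self.n_notes < 1:
            raise ContractError("n_notes must be positive")


@dataclass
class SyntheticCorpus:
    notes: list[NoteDocument]
    splits: dict[str, str]  # note_id -> "train" | "test"
    lexicons: LexiconSet
    manifest: dict = field(default_factory=dict)

    def split_notes(self, which: str) -> list[NoteDocument]:
        return [n for n in self.notes if self.splits[n.note_id] == which]


# sentence material; every character below must be present in the pinyin map
_FILLERS = (
    "患者一般情况可。",
    "精神饮食睡眠可。",
    "无发热。",
    "无咳嗽咳痰。",
    "无头晕头痛。",
    "无恶心呕吐。",
    "查体未见明显异常。",
    "双肺未见异常。",
    "大小便正常。",
    "否认食物过敏史。",
    "病情好转。",
    "患者未诉不适。",
    "家族史无特殊。",
    "发病以来体重无明显变化。",
)

_LAB_PLAIN = (
    "血常规未见异常。",
    "肝功能正常。",
    "肾功能正常。",
    "血钾3.8mmol/L。",
    "血钙2.3mmol/L。",
    "尿常规正常。",
)

# drug-like lab lines: dictionary terms in a non-medication context
_LAB_CONFUSABLE = (
    "地高辛0.7ng/ml。",
    "万古霉素浓度15mg/L。",
    "葡萄糖5.6mmol/L。",
)

_MED_PREFIXES = ("予以", "给予", "入院后予以", "继续予以", "")
_MED_TAILS = ("治疗。", "抗感染治疗。", "对症治疗。", "。", "治疗后好转。")

_SECTION_PLAN = (
    # (header, kind, min sentences, max sentences, inclusion probability)
    ("主诉", "filler", 1, 2, 1.0),
    ("现病史", "mixed", 3, 6, 1.0),
    ("既往史", "mixed", 2, 4, 1.0),
    ("家族史", "filler", 1, 2, 0.5),
    ("辅助检查", "lab", 2, 4, 1.0),
    ("用药情况", "mixed", 1, 3, 0.8),
    ("诊疗计划", "mixed", 1, 3, 0.6),
)


def _entity_pools(lexicons: LexiconSet, config: GeneratorConfig, rng: random.Random):
    wm = sorted(lexicons.wm_terms)[: config.n_wm_names]
    tcm = sorted(lexicons.tcm_terms)[: config.n_tcm_names]
    rng.shuffle(wm)
    rng.shuffle(tcm)
    n_hold_wm = round(config.held_out_fraction * len(wm))
    n_hold_tcm = round(config.held_out_fraction * len(tcm))
    held_wm, seen_wm = wm[:n_hold_wm], wm[n_hold_wm:]
    held_tcm, seen_tcm = tcm[:n_hold_tcm], tcm[n_hold_tcm:]
    if not seen_wm or not seen_tcm:
        raise ContractError("drug pools empty after held-out split")
    return (seen_wm, held_wm), (seen_tcm, held_tcm)


def _latin_alias(name: str, pinyin_map) -> str:
    sylls = [s for s in transliterate(name, pinyin_map) if s.isalpha()]
    return "".join(sylls).capitalize() or "Drug"


class _SentenceBuilder:
    """Concatenates parts while tracking entity spans."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.entities: list[tuple[int, int, EntityClass]] = []
        self._len = 0

    def add(self, text: str, cls: EntityClass | None = None) -> None:
        if text:
            if cls is not None:
                self.entities.append((self._len, self._len + len(text), cls))
            self.parts.append(text)
            self._len += len(text)

    def build(self) -> tuple[str, list[tuple[int, int, EntityClass]]]:
        return "".join(self.parts), self.entities


def _med_sentence(
    rng: random.Random,
    lexicons: LexiconSet,
    wm_pool: list[str],
    tcm_pool: list[str],
    config: GeneratorConfig,
) -> tuple[str, list[tuple[int, int, EntityClass]]]:
    b = _SentenceBuilder()
    b.add(rng.choice(_MED_PREFIXES))
    is_wm = rng.random() < config.wm_fraction
    if is_wm:
        name = rng.choice(wm_pool)
        if rng.random() < config.alias_rate:
            b.add("（" + _latin_alias(name, lexicons.pinyin_map) + "）")
        route = rng.choice(sorted(lexicons.routes_wm))
        dose = rng.choice(("0.25", "0.5", "1", "100", "250", "500")) + rng.choice(
            ("mg", "g", "ml")
        )
        freq = rng.choice(sorted(lexicons.freqs_wm))
        entity = name
        if rng.random() < 0.2:
            entity += rng.choice(sorted(lexicons.forms_wm))
        layout = rng.randrange(3)
        if layout == 0:
            b.add(route)
            b.add(entity, EntityClass.WM)
            b.add(dose)
            b.add(freq)
        elif layout == 1:
            b.add(entity, EntityClass.WM)
            b.add(dose)
            b.add(" " + route + " " if rng.random() < 0.3 else route)
            b.add(freq)
        else:
            b.add(entity, EntityClass.WM)
            b.add(freq)
            b.add(dose)
            b.add(route)
        if rng.random() < 0.15:  # a second, comma-separated drug
            b.add("、")
            b.add(rng.choice(wm_pool), EntityClass.WM)
            b.add(rng.choice(("0.5g", "250mg")))
    else:
        name = rng.choice(tcm_pool)
        entity = name
        if len(name) <= 3 and rng.random() < 0.3:
            entity += rng.choice(sorted(lexicons.forms_tcm))
        b.add("中药" if rng.random() < 0.3 else "")
        b.add(entity, EntityClass.TCM)
        b.add(rng.choice(("9克", "6克", "")))
        b.add(rng.choice(sorted(lexicons.freqs_tcm)))
        b.add(rng.choice(sorted(lexicons.routes_tcm)))
    b.add(rng.choice(_MED_TAILS))
    text, ents = b.build()
    if not text.endswith("。"):
        text += "。"
    return text, ents


def inject_typos(
    text: str,
    entities: list[tuple[int, int, EntityClass]],
    pinyin_map,
    rate: float,
    rng: random.Random | int,
) -> str:
    """Replace drug-name characters with homophones at the given rate.

    Spans are untouched (substitution is 1:1) and the transliteration of
    every substituted character is identical by construction.  ``rng`` may
    be a seed or a Random instance.
    """
    if isinstance(rng, int):
        rng = random.Random(rng)
    if rate <= 0:
        return text
    groups: dict[str, list[str]] = {}
    for ch, syll in pinyin_map.items():
        groups.setdefault(syll, []).append(ch)
    chars = list(text)
    for start, end, _cls in entities:
        for i in range(start, end):
            if rng.random() < rate:
                syll = pinyin_map.get(chars[i])
                if syll is None:
                    continue
                alts = [c for c in sorted(groups[syll]) if c != chars[i]]
                if alts:
                    chars[i] = rng.choice(alts)
    return "".join(chars)


def generate_corpus(
    config: GeneratorConfig, lexicons: LexiconSet | None = None
) -> SyntheticCorpus:
    """Generate an annotated corpus plus the lexicon set to analyze it with.

    Held-out drug names (``held_out_fraction``) appear only in test-split
    notes and are removed from the emitted dictionaries, so both the
    dictionary channels and the training data are blind to them.
    """
    base = lexicons if lexicons is not None else default_lexicons()
    if not base.wm_terms or not base.tcm_terms:
        raise ContractError("generate_corpus requires non-empty drug dictionaries")
    rng = random.Random(config.seed)
    (seen_wm, held_wm), (seen_tcm, held_tcm) = _entity_pools(base, config, rng)

    emitted = base.replace(
        wm_terms=frozenset(seen_wm), tcm_terms=frozenset(seen_tcm)
    )

    note_ids = [f"note-{i:04d}" for i in range(config.n_notes)]
    order = list(range(config.n_notes))
    rng.shuffle(order)
    n_train = round(config.train_fraction * config.n_notes)
    splits = {
        note_ids[j]: ("train" if k < n_train else "test")
        for k, j in enumerate(order)
    }

    notes: list[NoteDocument] = []
    stats = {"sentences": 0, "med_sentences": 0, "wm_entities": 0, "tcm_entities": 0}
    for note_id in note_ids:
        is_train = splits[note_id] == "train"
        wm_pool = seen_wm if is_train or not held_wm else seen_wm + held_wm
        tcm_pool = seen_tcm if is_train or not held_tcm else seen_tcm + held_tcm
        blocks: list[str] = []
        gold_queue: list[tuple[str, list[tuple[int, int, EntityClass]]]] = []
        for header, kind, lo, hi, p in _SECTION_PLAN:
            if rng.random() > p:
                continue
            blocks.append(header + "：\n")
            for _ in range(rng.randint(lo, hi)):
                stats["sentences"] += 1
                if rng.random() < config.med_sentence_rate:
                    text, ents = _med_sentence(rng, base, wm_pool, tcm_pool, config)
                    text = inject_typos(
                        text, ents, base.pinyin_map, config.typo_rate, rng
                    )
                    stats["med_sentences"] += 1
                    for _, _, cls in ents:
                        key = "wm_entities" if cls is EntityClass.WM else "tcm_entities"
                        stats[key] += 1
                elif kind == "lab":
                    pool = (
                        _LAB_CONFUSABLE
                        if rng.random() < config.lab_confusable_rate
                        else _LAB_PLAIN
                    )
                    text, ents = rng.choice(pool), []
                else:
                    text, ents = rng.choice(_FILLERS), []
                blocks.append(text)
                gold_queue.append((normalize_text(text), ents))
            blocks.append("\n")
        raw_text = "".join(blocks)
        note = preprocess_note(note_id, raw_text, base)
        _attach_gold(note, gold_queue)
        notes.append(note)

    total_ents = stats["wm_entities"] + stats["tcm_entities"]
    manifest = {
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "n_notes": config.n_notes,
        "n_sentences": stats["sentences"],
        "n_med_sentences": stats["med_sentences"],
        "realized_med_rate": stats["med_sentences"] / max(stats["sentences"], 1),
        "n_entities": total_ents,
        "realized_wm_fraction": stats["wm_entities"] / max(total_ents, 1),
        "held_out_wm": held_wm,
        "held_out_tcm": held_tcm,
    }
    return SyntheticCorpus(
        notes=notes, splits=splits, lexicons=emitted, manifest=manifest
    )


def _attach_gold(note: NoteDocument, gold_queue) -> None:
    qi = 0
    for k, rec in enumerate(note.sentences):
        if qi < len(gold_queue) and rec.chars == gold_queue[qi][0]:
            _, ents = gold_queue[qi]
            qi += 1
            if ents:
                anns = frozenset(
                    EntityAnnotation(
                        start=s, end=e, cls=cls, surface=rec.chars[s:e]
                    )
                    for s, e, cls in ents
                )
                note.sentences[k] = _dc_replace(rec, gold=anns)
    if qi != len(gold_queue):
        raise AssertionError(
            f"gold alignment failed in {note.note_id}: {qi}/{len(gold_queue)}"
        )


def make_abbreviation_cases(
    config: GeneratorConfig, lexicons: LexiconSet | None = None
) -> list[SentenceRecord]:
    """Compound-abbreviation sentences like 维生素A、C with two gold drugs.

    These are known-hard cases (the shared prefix is written once); they are
    flagged by note_id and meant to be excluded from headline scores.
    """
    import warnings

    base = lexicons if lexicons is not None else default_lexicons()
    rng = random.Random(config.seed)
    names = sorted(base.wm_terms | base.tcm_terms)
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            k = 0
            while k < min(len(a), len(b)) and a[k] == b[k]:
                k += 1
            if k >= 2 and len(a) > k and len(b) > k:
                pairs.append((a, b, k))
    if not pairs:
        warnings.warn("no shared-prefix drug pairs in the lexicon", stacklevel=2)
        return []
    out = []
    for a, b, k in sorted(pairs):
        first, second = (a, b) if rng.random() < 0.5 else (b, a)
        builder = _SentenceBuilder()
        builder.add("予以")
        cls_a = EntityClass.WM if first in base.wm_terms else EntityClass.TCM
        cls_b = EntityClass.WM if second in base.wm_terms else EntityClass.TCM
        builder.add(first, cls_a)
        builder.add("、")
        builder.add(second[k:], cls_b)
        builder.add("口服。")
        text, ents = builder.build()
        norm = normalize_text(text)
        rec = SentenceRecord(
            chars=norm,
            pinyin=transliterate(norm, base.pinyin_map),
            section="用药情况",
            note_id="abbrev-hard",
            gold=frozenset(
                EntityAnnotation(start=s, end=e, cls=c, surface=norm[s:e])
                for s, e, c in ents
            ),
        )
        out.append(rec)
    return out
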