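"""Character features, forward maximum matching, CRF contracts, baseline."""

import random

import pytest

from ccmer.matching import forward_max_match
from ccmer.ner import (
    FeatureConfig,
    NERModel,
    baseline_dict_recognize,
    extract_char_features,
    tag,
    train_crf,
)
from ccmer.preprocess import normalize_text, transliterate
from ccmer.resources import ContractError, SentenceRecord, TagSequence, encode_tags
from ccmer.synthetic import inject_typos


def record(text, lexicons, section=None, gold=frozenset()):
    norm = normalize_text(text)
    return SentenceRecord(
        chars=norm,
        pinyin=transliterate(norm, lexicons.pinyin_map),
        section=section,
        gold=gold,
    )


def brute_force_fmm(text, terms):
    """Independent oracle: try every term at every position, longest first."""
    spans = []
    i = 0
    while i < len(text):
        best = 0
        for t in terms:
            if len(t) > best and text[i : i + len(t)] == t:
                best = len(t)
        if best:
            spans.append((i, i + best))
            i += best
        else:
            i += 1
    return spans


class TestForwardMaxMatch:
    def test_longest_term_wins(self):
        assert forward_max_match("ABCD", {"AB", "ABC"}) == [(0, 3)]

    def test_interior_match(self):
        assert forward_max_match("XABY", {"AB"}) == [(1, 3)]

    def test_spans_never_overlap(self):
        rng = random.Random(0)
        for _ in range(200):
            text = "".join(rng.choice("ABCDE") for _ in range(30))
            terms = {
                "".join(rng.choice("ABCDE") for _ in range(rng.randint(1, 4)))
                for _ in range(5)
            }
            spans = forward_max_match(text, terms)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_matches_exhaustive_oracle(self):
        rng = random.Random(42)
        for _ in range(300):
            text = "".join(rng.choice("ABCDE") for _ in range(rng.randint(0, 30)))
            terms = {
                "".join(rng.choice("ABCDE") for _ in range(rng.randint(1, 4)))
                for _ in range(5)
            }
            assert forward_max_match(text, terms) == brute_force_fmm(text, terms)

    def test_works_on_syllable_tuples(self):
        text = ("en", "du", "zhi", "liao")
        assert forward_max_match(text, {("en", "du")}) == [(0, 2)]


class TestCharFeatures:
    def test_f1_window_grams(self, lexicons):
        rec = record("abc", lexicons)
        cfg = FeatureConfig(cws=1, enabled_groups=frozenset({"F1"}), f1_variant="chars")
        feats = extract_char_features(rec, lexicons, cfg)
        middle = set(feats[1])
        assert {
            "C1[-1]=a",
            "C1[0]=b",
            "C1[1]=c",
            "C2[-1]=a|b",
            "C2[0]=b|c",
            "C3[-1]=a|b|c",
        } == middle

    def test_boundary_positions_padded(self, lexicons):
        rec = record("ab", lexicons)
        cfg = FeatureConfig(cws=1, enabled_groups=frozenset({"F1"}), f1_variant="chars")
        feats = extract_char_features(rec, lexicons, cfg)
        assert "C1[-1]=<S>" in feats[0]
        assert "C1[1]=</S>" in feats[1]

    def test_dictionary_span_covers_every_character(self, lexicons):
        rec = record("予以黄芪治疗", lexicons)
        cfg = FeatureConfig(enabled_groups=frozenset({"F2"}))
        feats = extract_char_features(rec, lexicons, cfg)
        assert "F2-InDictTCM" in feats[2]
        assert "F2-InDictTCM" in feats[3]
        assert "F2-InDictTCM" not in feats[0]

    def test_digit_flag_spans_window(self, lexicons):
        rec = record("用9克", lexicons)
        cfg = FeatureConfig(enabled_groups=frozenset({"F4"}))
        feats = extract_char_features(rec, lexicons, cfg)
        assert all("F4-HasNum9" in f for f in feats)

    def test_section_features(self, lexicons):
        rec = record("地高辛", lexicons, section="辅助检查")
        cfg = FeatureConfig(enabled_groups=frozenset({"F5"}))
        feats = extract_char_features(rec, lexicons, cfg)
        assert "F5-InListSectionName" in feats[0]
        assert "F5-Section=辅助检查" in feats[0]

    def test_extraction_is_pure(self, lexicons):
        rec = record("予以恩度0.5g静滴QD", lexicons, section="现病史")
        a = extract_char_features(rec, lexicons)
        b = extract_char_features(rec, lexicons)
        assert a == b

    def test_invalid_cws_rejected(self):
        with pytest.raises(ContractError):
            FeatureConfig(cws=4)


def _training_pairs(lexicons, texts_and_spans):
    sents, tags = [], []
    from ccmer.resources import EntityAnnotation, EntityClass

    for text, spans in texts_and_spans:
        gold = frozenset(
            EntityAnnotation(s, e, EntityClass(c), normalize_text(text)[s:e])
            for s, e, c in spans
        )
        rec = record(text, lexicons, section="现病史", gold=gold)
        sents.append(rec)
        tags.append(encode_tags(rec))
    return sents, tags


class TestCRF:
    def test_memorizes_repeated_template(self, lexicons):
        pairs = [("予以恩度0.5g静滴治疗。", [(2, 4, "WM")])] * 20
        sents, tags = _training_pairs(lexicons, pairs)
        model = train_crf(sents, tags, lexicons, maxiter=60)
        assert tuple(tag(model, sents[0], lexicons)) == tags[0].labels

    def test_same_seed_identical_predictions(self, lexicons):
        pairs = [
            ("予以恩度0.5g静滴治疗。", [(2, 4, "WM")]),
            ("予以黄芪汤每日一剂水煎服。", [(2, 5, "TCM")]),
        ] * 5
        sents, tags = _training_pairs(lexicons, pairs)
        held_out = record("予以恩度0.5g口服。", lexicons, section="现病史")
        m1 = train_crf(sents, tags, lexicons, seed=1, maxiter=40)
        m2 = train_crf(sents, tags, lexicons, seed=1, maxiter=40)
        assert tuple(tag(m1, held_out, lexicons)) == tuple(tag(m2, held_out, lexicons))

    def test_tagging_is_length_preserving(self, lexicons):
        pairs = [("予以恩度0.5g静滴治疗。", [(2, 4, "WM")])] * 10
        sents, tags = _training_pairs(lexicons, pairs)
        model = train_crf(sents, tags, lexicons, maxiter=30)
        for text in ("甲乙丙", "予以恩度", "。"):
            rec = record(text, lexicons)
            assert len(tag(model, rec, lexicons)) == len(rec.chars)

    def test_empty_training_set_rejected(self, lexicons):
        with pytest.raises(ContractError):
            train_crf([], [], lexicons)

    def test_model_round_trip(self, lexicons, tmp_path):
        pairs = [("予以恩度0.5g静滴治疗。", [(2, 4, "WM")])] * 10
        sents, tags = _training_pairs(lexicons, pairs)
        model = train_crf(sents, tags, lexicons, maxiter=30)
        p = tmp_path / "crf.json"
        model.save(p)
        back = NERModel.load(p)
        rec = record("予以恩度0.5g静滴治疗。", lexicons, section="现病史")
        assert tuple(tag(back, rec, lexicons)) == tuple(tag(model, rec, lexicons))

    def test_config_mismatch_rejected(self, lexicons):
        pairs = [("予以恩度0.5g静滴治疗。", [(2, 4, "WM")])] * 5
        sents, tags = _training_pairs(lexicons, pairs)
        model = train_crf(sents, tags, lexicons, maxiter=20)
        rec = record("予以恩度", lexicons)
        with pytest.raises(ContractError):
            tag(model, rec, lexicons, config=FeatureConfig(cws=1))


class TestBaselineDict:
    def test_verbatim_name_exact_span(self, lexicons):
        rec = record("予以阿莫西林口服。", lexicons)
        ents = baseline_dict_recognize(rec, lexicons)
        assert any(
            (e.start, e.end, e.cls.value) == (2, 6, "WM") for e in ents
        )

    def test_homophone_typo_found_via_pinyin(self, lexicons):
        clean = "予以恩度静滴。"
        typo_text = inject_typos(clean, [(2, 4, None)], lexicons.pinyin_map, 1.0, 9)
        assert typo_text != clean
        rec = record(typo_text, lexicons)
        chars_only = baseline_dict_recognize(rec, lexicons, use_pinyin=False)
        with_pinyin = baseline_dict_recognize(rec, lexicons)
        assert not any(e.start == 2 for e in chars_only)
        assert any((e.start, e.end) == (2, 4) for e in with_pinyin)

    def test_no_match_empty(self, lexicons):
        rec = record("今天天气好。", lexicons)
        # (the pinyin channel may fire on coincidental syllables; characters
        # here are chosen to avoid any dictionary term's pinyin)
        assert baseline_dict_recognize(rec, lexicons) == frozenset()

    def test_output_spans_non_overlapping(self, lexicons):
        rec = record("予以恩度恩度阿莫西林口服。", lexicons)
        ents = sorted(baseline_dict_recognize(rec, lexicons))
        for a, b in zip(ents, ents[1:]):
            assert a.end <= b.start
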