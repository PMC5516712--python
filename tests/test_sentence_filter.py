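"""The 6-d sentence feature vector and the hot-sentence classifier."""

import numpy as np
import pytest

from ccmer.feature_mining import WeightedKeywordList
from ccmer.preprocess import normalize_text, transliterate
from ccmer.resources import ContractError, SentenceRecord
from ccmer.sentence_filter import (
    EventPatternMatcher,
    FilterModel,
    classify_sentences,
    extract_sf_vector,
    match_event_patterns,
    train_filter,
)
from ccmer.synthetic import inject_typos


def record(text, lexicons, section=None):
    norm = normalize_text(text)
    return SentenceRecord(
        chars=norm, pinyin=transliterate(norm, lexicons.pinyin_map), section=section
    )


@pytest.fixture(scope="module")
def keyword_lists():
    # 9/200 = 0.045 exactly; the filler keyword never occurs in test text
    pos = WeightedKeywordList(
        entries=(("予以", 9, 0.045), ("患者", 191, 0.955)), polarity="positive"
    )
    neg = WeightedKeywordList(entries=(("未见", 5, 1.0),), polarity="negative")
    return pos, neg


@pytest.fixture(scope="module")
def matcher(lexicons):
    return EventPatternMatcher(lexicons)


class TestExtractSfVector:
    def test_worked_medication_sentence(self, lexicons, keyword_lists, matcher):
        """An engineered prescription line yields (2, 2, 2, 0.045, 0, 4):
        two bracket symbols, two dictionary hits, their two pinyin hits,
        one positive keyword of weight 0.045, no negative keywords, and
        four event-pattern matches."""
        pos, neg = keyword_lists
        rec = record("予以（氧氟沙星）口服左氧氟沙星片QD0.5g", lexicons)
        v = extract_sf_vector(rec, lexicons, pos, neg, matcher)
        assert v.as_tuple() == (2, 2, 2, 0.045, 0, 4)

    def test_empty_sentence_is_zero(self, lexicons, keyword_lists, matcher):
        pos, neg = keyword_lists
        rec = SentenceRecord(chars="", pinyin=())
        v = extract_sf_vector(rec, lexicons, pos, neg, matcher)
        assert v.as_tuple() == (0, 0, 0, 0, 0, 0)

    def test_keyword_weight_multiplies_by_occurrences(
        self, lexicons, keyword_lists, matcher
    ):
        pos, neg = keyword_lists
        rec = record("予以甲药预后再予以乙药", lexicons)
        v2 = extract_sf_vector(rec, lexicons, pos, neg, matcher)
        assert v2.sf4 == pytest.approx(2 * 0.045)
        once = extract_sf_vector(
            rec, lexicons, pos, neg, matcher, count_keyword_occurrences=False
        )
        assert once.sf4 == pytest.approx(0.045)

    def test_position_in_note_is_irrelevant(self, lexicons, keyword_lists, matcher):
        pos, neg = keyword_lists
        a = record("予以恩度静滴", lexicons)
        b = record("予以恩度静滴", lexicons)
        b.note_id = "other-note"
        va = extract_sf_vector(a, lexicons, pos, neg, matcher)
        vb = extract_sf_vector(b, lexicons, pos, neg, matcher)
        assert va == vb

    def test_homophone_typo_keeps_pinyin_hit(self, lexicons, keyword_lists, matcher):
        """Swapping a drug-name character for a homophone may lose the
        character-dictionary hit but never the pinyin hit."""
        pos, neg = keyword_lists
        clean = record("予以恩度静滴", lexicons)
        typo_text = inject_typos(
            clean.chars, [(2, 4, None)], lexicons.pinyin_map, 1.0, 123
        )
        assert typo_text != clean.chars
        typo = record(typo_text, lexicons)
        v_clean = extract_sf_vector(clean, lexicons, pos, neg, matcher)
        v_typo = extract_sf_vector(typo, lexicons, pos, neg, matcher)
        assert v_typo.sf3 == v_clean.sf3
        assert v_typo.sf2 <= v_clean.sf2

    def test_missing_keyword_lists_rejected(self, lexicons, matcher):
        rec = record("予以恩度", lexicons)
        with pytest.raises(ContractError):
            extract_sf_vector(rec, lexicons, None, None, matcher)


class TestEventPatterns:
    def test_number_dose_template(self, lexicons, matcher):
        rec = record("0.5 g", lexicons)
        assert match_event_patterns(rec, matcher) >= 1

    def test_frequency_alone(self, lexicons, matcher):
        rec = record("Q.D", lexicons)
        assert match_event_patterns(rec, matcher) == 1

    def test_no_lexicon_terms_no_matches(self, lexicons, matcher):
        rec = record("甲乙丙丁", lexicons)
        assert match_event_patterns(rec, matcher) == 0


class TestFilterTraining:
    def _toy(self, n_neg=20, n_pos=10):
        rng = np.random.default_rng(0)
        neg = np.zeros((n_neg, 6))
        pos = np.zeros((n_pos, 6))
        pos[:, 1] = rng.integers(1, 3, n_pos)  # sf2 > 0
        pos[:, 5] = rng.integers(1, 4, n_pos)
        X = np.vstack([neg, pos])
        y = np.array([False] * n_neg + [True] * n_pos)
        return X, y

    def test_separable_set_fit_exactly(self):
        X, y = self._toy()
        model = train_filter(X, y, seed=0)
        assert (classify_sentences(model, X) == y).all()

    def test_same_seed_same_weights(self):
        X, y = self._toy()
        m1 = train_filter(X, y, seed=3)
        m2 = train_filter(X, y, seed=3)
        assert np.array_equal(m1.weights, m2.weights)
        assert m1.bias == m2.bias

    def test_class_weighting_helps_minority_recall(self):
        rng = np.random.default_rng(5)
        n_neg, n_pos = 400, 20
        X = np.vstack(
            [
                rng.normal(0.0, 0.6, (n_neg, 6)).clip(0),
                rng.normal(1.0, 0.6, (n_pos, 6)).clip(0),
            ]
        )
        y = np.array([False] * n_neg + [True] * n_pos)
        balanced = train_filter(X, y, {"class_weight": "balanced"}, seed=0)
        unweighted = train_filter(X, y, {"class_weight": None}, seed=0)
        rec_b = (classify_sentences(balanced, X) & y).sum() / y.sum()
        rec_u = (classify_sentences(unweighted, X) & y).sum() / y.sum()
        assert rec_b >= rec_u

    def test_single_class_rejected(self):
        X = np.zeros((5, 6))
        with pytest.raises(ContractError):
            train_filter(X, [False] * 5, seed=0)

    def test_serialization_round_trip(self, tmp_path):
        X, y = self._toy()
        model = train_filter(X, y, seed=0)
        p = tmp_path / "filter.json"
        model.save(p)
        back = FilterModel.load(p)
        assert np.array_equal(back.weights, model.weights)
        assert back.bias == model.bias


class TestClassify:
    def test_zero_vector_with_negative_bias(self):
        model = FilterModel(weights=np.ones(6), bias=-1.0)
        assert not classify_sentences(model, np.zeros((1, 6)))[0]

    def test_worked_vector_is_medication(self):
        model = FilterModel(weights=np.ones(6), bias=-1.0)
        v = np.array([[2, 2, 2, 0.045, 0, 4]], dtype=float)
        assert classify_sentences(model, v)[0]

    def test_dimension_mismatch_rejected(self):
        model = FilterModel(weights=np.ones(6), bias=0.0)
        with pytest.raises(ContractError):
            classify_sentences(model, np.zeros((2, 4)))
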