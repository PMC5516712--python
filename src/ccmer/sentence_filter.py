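"""Hot-sentence filter: 6-d feature vectors and a hinge-loss linear model.

Each sentence is mapped to a six-dimensional vector

* SF1 — count of formal symbols from the symbol list,
* SF2 — occurrences of dictionary drug terms in the characters,
* SF3 — occurrences of the terms' pinyin in the sentence's pinyin,
* SF4 — summed weights of positive statistical keywords,
* SF5 — summed weights of negative statistical keywords,
* SF6 — count of drug-use event-pattern matches,

and classified MEDICATION / NO-MEDICATION by a linear max-margin model
trained with stochastic gradient descent.  Only MEDICATION sentences flow
to the character-level tagger, which shields it from the ~1:25
negative-to-positive sentence imbalance of admission notes.

The pinyin channel (SF3) makes the filter robust to homophone typos: a
misspelled drug name loses its SF2 hit but keeps its SF3 hit because the
wrong character shares the intended character's pronunciation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import SGDClassifier

from .feature_mining import WeightedKeywordList, count_occurrences
from .matching import forward_max_match
from .preprocess import transliterate
from .resources import ContractError, LexiconSet, SentenceRecord

#: translation table folding full-width ASCII variants onto ASCII.
_FULLWIDTH = {code + 0xFEE0: code for code in range(0x21, 0x7F)}


def _fold_width(s: str) -> str:
    return s.translate(_FULLWIDTH)


@dataclass(frozen=True)
class SentenceFeatureVector:
    sf1: float  # symbol count
    sf2: float  # dictionary-term occurrences (characters)
    sf3: float  # dictionary-term occurrences (pinyin)
    sf4: float  # positive keyword weight sum
    sf5: float  # negative keyword weight sum
    sf6: float  # event-pattern matches

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.as_array()):
            raise ContractError("feature components must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sf1, self.sf2, self.sf3, self.sf4, self.sf5, self.sf6], dtype=float
        )

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(self.as_array())


class EventPatternMatcher:
    """The five drug-use collocation template families.

    1. number + dose unit            (numbers are ``9``-runs post-normalization)
    2. route-of-administration term
    3. frequency term
    4. route term directly followed by a dictionary drug name
    5. dictionary drug name directly followed by a frequency term

    Matches are non-overlapping within each family; families are counted
    independently and summed (a route that also begins a route+name
    collocation counts in both families).
    """

    _NUMBER = r"9+(?:[.．]9+)?"

    def __init__(self, lexicons: LexiconSet):
        self.lexicons = lexicons
        dose = sorted(lexicons.dose_units_wm | lexicons.dose_units_tcm, key=len, reverse=True)
        route = sorted(lexicons.routes_wm | lexicons.routes_tcm, key=len, reverse=True)
        freq = sorted(lexicons.freqs_wm | lexicons.freqs_tcm, key=len, reverse=True)
        self._dose_re = _alternation(f"(?:{self._NUMBER})\\s*", dose)
        self._route_re = _alternation("", route)
        self._freq_re = _alternation("", freq)
        self._routes = route
        self._freqs = freq
        self._drug_terms = frozenset(lexicons.all_drug_terms())

    def count(self, chars: str) -> int:
        total = 0
        for rx in (self._dose_re, self._route_re, self._freq_re):
            if rx is not None:
                total += sum(1 for _ in rx.finditer(chars))
        spans = forward_max_match(chars, self._drug_terms)
        for start, end in spans:
            before = chars[:start].rstrip()
            if any(before.endswith(r) for r in self._routes):
                total += 1  # family 4: route + name
            after = chars[end:].lstrip()
            if any(after.startswith(f) for f in self._freqs):
                total += 1  # family 5: name + frequency
        return total


def _alternation(prefix: str, terms: list[str]) -> re.Pattern | None:
    if not terms:
        return None
    body = "|".join(re.escape(t) for t in terms)
    return re.compile(f"{prefix}(?:{body})")


def match_event_patterns(sentence: SentenceRecord, matcher: EventPatternMatcher) -> int:
    """Total non-overlapping matches of the five template families."""
    return matcher.count(sentence.chars)


def pinyin_of_term(term: str, pinyin_map) -> tuple[str, ...]:
    return transliterate(term, pinyin_map)


def extract_sf_vector(
    sentence: SentenceRecord,
    lexicons: LexiconSet,
    pos_list: WeightedKeywordList,
    neg_list: WeightedKeywordList,
    matcher: EventPatternMatcher | None = None,
    count_keyword_occurrences: bool = True,
) -> SentenceFeatureVector:
    """Map a sentence to its 6-dimensional filter feature vector."""
    if pos_list is None or neg_list is None:
        raise ContractError("keyword lists are required")
    if matcher is None:
        matcher = EventPatternMatcher(lexicons)
    chars = sentence.chars

    folded = _fold_width(chars)
    # width-fold the symbol list into a canonical set so that e.g. （ and (
    # count the same occurrence once
    folded_syms = {_fold_width(sym) for sym in lexicons.symbol_list}
    sf1 = sum(count_occurrences(sym, folded) for sym in folded_syms)

    drug_terms = lexicons.all_drug_terms()
    sf2 = len(forward_max_match(chars, drug_terms))

    term_pinyin = {pinyin_of_term(t, lexicons.pinyin_map) for t in drug_terms}
    sf3 = len(forward_max_match(tuple(sentence.pinyin), term_pinyin))

    def weight_sum(kwlist: WeightedKeywordList) -> float:
        total = 0.0
        for kw, _, w in kwlist.entries:
            occ = count_occurrences(kw, chars)
            if occ:
                total += w * (occ if count_keyword_occurrences else 1)
        return total

    sf4 = weight_sum(pos_list)
    sf5 = weight_sum(neg_list)
    sf6 = matcher.count(chars)
    return SentenceFeatureVector(sf1, sf2, sf3, sf4, sf5, sf6)


@dataclass
class FilterModel:
    """Linear max-margin sentence classifier: sign(w·x + b)."""

    weights: np.ndarray  # shape (6,)
    bias: float
    hyperparams: dict = field(default_factory=dict)

    def decision(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 2 or vectors.shape[1] != self.weights.shape[0]:
            raise ContractError(
                f"expected (n, {self.weights.shape[0]}) feature matrix, "
                f"got {vectors.shape}"
            )
        return vectors @ self.weights + self.bias

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "ccmer-filter-v1",
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "hyperparams": self.hyperparams,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "FilterModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            weights=np.array(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            hyperparams=payload.get("hyperparams", {}),
        )


DEFAULT_FILTER_HYPERPARAMS = {
    "alpha": 1e-4,
    "max_iter": 1000,
    "tol": 1e-4,
    "class_weight": "balanced",
}


def train_filter(
    vectors: Sequence[SentenceFeatureVector] | np.ndarray,
    labels: Sequence[bool],
    hyperparams: dict | None = None,
    seed: int = 0,
) -> FilterModel:
    """Train the hinge-loss linear model by stochastic gradient descent.

    ``class_weight="balanced"`` (the default) counteracts the strong
    negative-sentence majority.  Same data and seed give identical weights.
    """
    X = _to_matrix(vectors)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ContractError("training set must contain both classes")
    hp = dict(DEFAULT_FILTER_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    clf = SGDClassifier(
        loss="hinge",
        alpha=hp["alpha"],
        max_iter=hp["max_iter"],
        tol=hp["tol"],
        class_weight=hp["class_weight"],
        random_state=seed,
    )
    clf.fit(X, y)
    return FilterModel(
        weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]), hyperparams=hp
    )


def classify_sentences(
    model: FilterModel, vectors: Sequence[SentenceFeatureVector] | np.ndarray
) -> np.ndarray:
    """Binary MEDICATION labels (margin threshold 0); True = medication."""
    X = _to_matrix(vectors)
    return model.decision(X) > 0


def _to_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return np.atleast_2d(vectors.astype(float))
    return np.array([v.as_array() for v in vectors], dtype=float)
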