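"""End-to-end orchestration: preprocess → filter → tag → repair → evaluate.

`train_pipeline` fits the keyword lists, the hot-sentence filter and the
CRF tagger on a corpus's training split; `run_pipeline` applies the cascade
to the test split and scores it with the soft boundary-aware metric.
Switches reproduce the reference configurations: ``use_filter=False`` runs
the tagger over every sentence (the no-filtration baseline), a restricted
``FeatureConfig`` reproduces the local-context-only baseline, and
``baseline_dict`` bypasses learning entirely with dictionary maximum
matching.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluate import EvalReport, corpus_soft_prf, filter_confusion
from .feature_mining import WeightedKeywordList, compute_weights, mine_keywords
from .ner import FeatureConfig, NERModel, baseline_dict_recognize, tag, train_crf
from .postprocess import balance_parentheses, repair_bio
from .resources import (
    ContractError,
    LexiconSet,
    SentenceRecord,
    TagSequence,
    decode_entities,
    encode_tags,
)
from .sentence_filter import (
    EventPatternMatcher,
    FilterModel,
    classify_sentences,
    extract_sf_vector,
    train_filter,
)
from .synthetic import SyntheticCorpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    feature_config: FeatureConfig = FeatureConfig()
    use_filter: bool = True
    filter_hyperparams: dict | None = None
    crf_c2: float = 0.1
    crf_maxiter: int = 80
    retain_fraction: float = 0.3
    min_count: int = 2
    count_keyword_occurrences: bool = True
    rule2_keep_class: bool = False
    postprocess: bool = True
    seed: int = 0


@dataclass
class TrainedPipeline:
    config: PipelineConfig
    lexicons: LexiconSet
    pos_list: WeightedKeywordList
    neg_list: WeightedKeywordList
    filter_model: FilterModel | None
    ner_model: NERModel
    matcher: EventPatternMatcher = field(repr=False, default=None)


def _sentences_of(notes) -> list[SentenceRecord]:
    return [s for note in notes for s in note.sentences]


def mine_keyword_lists(
    sentences: list[SentenceRecord],
    retain_fraction: float = 0.3,
    min_count: int = 2,
) -> tuple[WeightedKeywordList, WeightedKeywordList]:
    pos_texts = [s.chars for s in sentences if s.gold]
    neg_texts = [s.chars for s in sentences if not s.gold]
    if not pos_texts or not neg_texts:
        raise ContractError("need both medication and plain sentences to mine")
    pos = compute_weights(
        mine_keywords(pos_texts, retain_fraction, min_count), "positive"
    )
    neg = compute_weights(
        mine_keywords(neg_texts, retain_fraction, min_count), "negative"
    )
    return pos, neg


def train_pipeline(corpus: SyntheticCorpus, config: PipelineConfig) -> TrainedPipeline:
    lex = corpus.lexicons
    train_sents = _sentences_of(corpus.split_notes("train"))
    if not train_sents:
        raise ContractError("empty training split")
    pos, neg = mine_keyword_lists(
        train_sents, config.retain_fraction, config.min_count
    )
    matcher = EventPatternMatcher(lex)
    vectors = [
        extract_sf_vector(
            s, lex, pos, neg, matcher, config.count_keyword_occurrences
        )
        for s in train_sents
    ]
    labels = [bool(s.gold) for s in train_sents]

    filter_model = None
    if config.use_filter:
        filter_model = train_filter(
            vectors, labels, config.filter_hyperparams, seed=config.seed
        )
        keep = classify_sentences(filter_model, vectors)
        crf_sents = [s for s, k in zip(train_sents, keep) if k]
        logger.info(
            "filter kept %d/%d training sentences", len(crf_sents), len(train_sents)
        )
        if not crf_sents:  # degenerate filter; fall back to gold-positive set
            crf_sents = [s for s in train_sents if s.gold]
    else:
        crf_sents = train_sents
    tags = [encode_tags(s) for s in crf_sents]
    ner_model = train_crf(
        crf_sents,
        tags,
        lex,
        config.feature_config,
        c2=config.crf_c2,
        maxiter=config.crf_maxiter,
        seed=config.seed,
    )
    logger.info("CRF trained on %d sentences", len(crf_sents))
    return TrainedPipeline(
        config=config,
        lexicons=lex,
        pos_list=pos,
        neg_list=neg,
        filter_model=filter_model,
        ner_model=ner_model,
        matcher=matcher,
    )


def predict_sentences(
    pipe: TrainedPipeline, sentences: list[SentenceRecord]
) -> tuple[list[TagSequence], list[frozenset], np.ndarray]:
    """Tag sentences through the cascade; filtered-out sentences are all-O."""
    cfg = pipe.config
    if cfg.use_filter and pipe.filter_model is not None:
        vectors = [
            extract_sf_vector(
                s,
                pipe.lexicons,
                pipe.pos_list,
                pipe.neg_list,
                pipe.matcher,
                cfg.count_keyword_occurrences,
            )
            for s in sentences
        ]
        keep = classify_sentences(pipe.filter_model, vectors)
    else:
        keep = np.ones(len(sentences), dtype=bool)
    tag_seqs: list[TagSequence] = []
    entity_sets: list[frozenset] = []
    for s, k in zip(sentences, keep):
        if not k or not s.chars:
            tags = TagSequence(tuple("O" for _ in s.chars))
        else:
            tags = tag(pipe.ner_model, s, pipe.lexicons)
            if cfg.postprocess:
                tags, _ = repair_bio(tags, cfg.rule2_keep_class)
                tags = balance_parentheses(tags, s.chars)
            else:
                # rules 1-2 only: the minimum coercion that makes a raw
                # decode BIO-valid for entity extraction
                tags, _ = repair_bio(tags, cfg.rule2_keep_class, merge_adjacent=False)
        tag_seqs.append(tags)
        entity_sets.append(decode_entities(tags, s))
    return tag_seqs, entity_sets, keep


def run_pipeline(
    corpus: SyntheticCorpus,
    config: PipelineConfig,
    baseline_dict: bool = False,
    pipe: TrainedPipeline | None = None,
) -> dict:
    """Train (unless given) and evaluate on the corpus test split."""
    test_sents = _sentences_of(corpus.split_notes("test"))
    gold_sets = [frozenset(s.gold) for s in test_sents]
    if baseline_dict:
        pred_sets = [baseline_dict_recognize(s, corpus.lexicons) for s in test_sents]
        report = corpus_soft_prf(gold_sets, pred_sets)
        return {"report": report, "n_sentences": len(test_sents), "pipe": None}
    if pipe is None:
        pipe = train_pipeline(corpus, config)
    _, pred_sets, keep = predict_sentences(pipe, test_sents)
    report = corpus_soft_prf(gold_sets, pred_sets)
    confusion = filter_confusion([bool(g) for g in gold_sets], list(map(bool, keep)))
    logger.info(
        "test: %d sentences, %d passed filter, soft F = %.3f",
        len(test_sents),
        int(keep.sum()),
        report.f_measure,
    )
    return {
        "report": report,
        "confusion": confusion,
        "n_sentences": len(test_sents),
        "pipe": pipe,
    }


def ablation_sweep(
    corpus_factory,
    grid: list[tuple[str, PipelineConfig]],
    seeds: list[int],
) -> list[dict]:
    """Evaluate a configuration grid across seeds.

    ``corpus_factory(seed)`` must return a SyntheticCorpus.  Returns one row
    per grid entry with per-seed F values, mean and standard deviation.
    """
    if not grid:
        raise ContractError("empty configuration grid")
    rows = []
    per_seed_f: dict[str, list[float]] = {name: [] for name, _ in grid}
    for seed in seeds:
        corpus = corpus_factory(seed)
        for name, cfg in grid:
            result = run_pipeline(corpus, replace(cfg, seed=seed))
            per_seed_f[name].append(result["report"].f_measure)
    for name, cfg in grid:
        fs = per_seed_f[name]
        rows.append(
            {
                "name": name,
                "cws": cfg.feature_config.cws,
                "groups": sorted(cfg.feature_config.enabled_groups),
                "use_filter": cfg.use_filter,
                "f_per_seed": fs,
                "f_mean": statistics.fmean(fs),
                "f_sd": statistics.stdev(fs) if len(fs) > 1 else 0.0,
                "n_seeds": len(fs),
            }
        )
    return rows
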