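# Methods

This note records the modeling decisions behind `ccmer`, the defaults that
matter, and what the synthetic experiments do and do not establish.

## Problem setting

The task is medication named-entity recognition in Chinese admission
notes, with two entity classes: Western-medicine drug names (largely
transliterations, e.g. 左氧氟沙星) and traditional-Chinese-medicine names
(herbs and patent drugs, e.g. 黄芪, 大青龙汤). Three properties of the
domain drive the design. First, word segmenters trained on general Chinese
fail on clinical text, so all modeling is at the character level. Second,
drug mentions are rare — on the order of 4% of sentences — so a sequence
tagger trained on raw notes drowns in negatives; the cascade interposes a
sentence-level filter. Third, notes are written with pinyin input methods,
so misspellings are overwhelmingly homophones; every dictionary channel
therefore exists twice, once over characters and once over toneless
pinyin.

## Preprocessing

`normalize_text` maps every decimal digit (ASCII and full-width) to `9`
and every Greek letter (plus U+00B5 micro) to `@`. The map is 1:1 by
construction, which makes normalization idempotent and offset-preserving —
gold spans computed on raw text remain valid afterwards. Sentence
terminators are {。；！？, newline}; comma splitting is opt-in
(`split_clauses`) because clause boundaries are not well defined in
telegraphic clinical prose. Stopwords are never removed: transliterated WM
names are full of function characters (的/尔/他…), and removal would
destroy entity surfaces. The pinyin map ships as a two-column TSV of ~530
common clinical characters with one (clinically dominant) reading per
character; unmapped CJK characters transliterate to a sentinel and are
logged once. Tone marks are dropped and ü is written `lv`.

## Sentence filter

Each sentence becomes the 6-vector ⟨SF1…SF6⟩:

* SF1 counts formal symbols (brackets, angle quotes) with multiplicity,
  after folding full-width ASCII variants so （ and ( count as one symbol
  type.
* SF2 counts drug-dictionary occurrences via a non-overlapping
  left-to-right longest-match scan; SF3 is the same scan on the syllable
  sequence against the dictionary terms' pinyin.
* SF4/SF5 sum the weights of mined positive/negative keywords, weight ×
  occurrence count (the alternative — counting each keyword once — is a
  switch, `count_keyword_occurrences=False`).
* SF6 counts five collocation template families: number+dose-unit,
  route, frequency, route+name, name+frequency. Matches are
  non-overlapping within a family and summed across families, so a route
  that also opens a route+name collocation contributes to both — this is
  what makes a dense prescription clause score 4.

Keyword mining counts every 2/3/4-gram (equivalent to extending frequent
bigrams by their overlapping successors, since occurrence counts are
monotone under prefix), drops grams crossing whitespace, keeps grams with
count ≥ 2, ranks by count with a lexicographic tiebreak, and retains the
top 30%. Weights normalize counts over the retained list.

The classifier is a hinge-loss linear model fit by stochastic gradient
descent (scikit-learn's `SGDClassifier`), `class_weight="balanced"` by
default to counter the ~25:1 imbalance, decision threshold 0 on the
margin, no probability calibration. Training is deterministic given the
seed.

## Character tagger

The tagger is a linear-chain CRF over the five labels
{O, B-WM, I-WM, B-TCM, I-TCM}, written in-package: state features are
interned strings, the objective is the L2-penalized negative
log-likelihood (default c2 = 0.1), optimized with scipy's L-BFGS-B
(default 80 iterations). Forward–backward runs batched over all sentences
padded to the longest with carry-forward masking, and emission
scores/gradients flow through one sparse matrix product per iteration, so
training on a few thousand short sentences takes seconds on one core.
There is no randomness in the objective; the `seed` argument exists for
interface symmetry and reproducibility bookkeeping.

Feature families per character, at context window size (CWS) ≤ 3 —
larger windows add noise in short clinical clauses:

* **F1** 1/2/3-grams of characters and (default) pinyin inside the
  window. The printed inventory of 3-gram templates this follows is
  asymmetric at the right window edge; the implementation uses the
  symmetric completion (3-gram start offsets −cws … cws−2).
* **F2** four membership flags from forward-maximum-match spans of the
  TCM/WM dictionaries on characters and pinyin; every covered character is
  flagged, not just the span start. Enabled but not in the default set:
  with small dictionaries its signal duplicates F1, and the default
  feature set (F1+F3+F4+F5+F6) is the configuration found best in
  ablations.
* **F3** sixteen flags crossing {dose, route, form, frequency} ×
  {TCM, WM} × {a term starts in i…i+3, a term starts in i−3…i−1}.
* **F4** window flags for digit `9`, `@`, Latin letters, and time
  expressions (`9`-runs followed by 时/日/周/月/年/天/分/秒, `h`, `d` —
  a configurable pattern, since no canonical inventory exists).
* **F5** whether the owning section header is in the configured list,
  plus the header itself as a feature value.
* **F6** label history. A first-order CRF cannot observe its own previous
  predictions as input features, so by default the category of preceding
  characters is realized by the chain's label-bigram transition weights.
  An optional greedy mode (`f6_observed=True`) injects the previous three
  labels as observation features — gold at training time, predicted at
  inference — and decodes left-to-right instead of with Viterbi.

## BIO repair

Rules, applied left to right in one pass: (1) `O I-X` → `O B-X`;
(2) cross-class `I` after `B`/`I` becomes a `B` of the *preceding* class —
the printed rewrite example (B-WM I-TCM → B-WM B-WM) coerces the class,
and that example is followed; `rule2_keep_class=True` selects the prose
reading instead; (3) a `B-X` immediately continuing an `I-X` run merges
into it. Rule 3 triggers only on I-before-B: merging B-after-B would turn
rule 2's printed output into B-WM I-WM on a second pass, breaking both the
example and idempotence. A rule-2 rewrite is itself re-checked against
rule 3, which makes `repair_bio` idempotent (property-tested). Repairs
relabel only — length is invariant — and a replayable trace is returned.

Parenthesis balancing: an entity containing ) without ( extends leftward
to the nearest ( (unchanged if none exists); an O-labeled ) immediately
after an entity is absorbed; an entity starting with an unmatched ( drops
it. The final clause of the printed rule 5 is grammatically ambiguous; the
strip-leading-( reading is implemented. Full-width （） and ASCII () are
equivalent throughout.

## Soft evaluation

Predictions and golds are paired greedily one-to-one among same-class
overlapping spans in descending character overlap (ties: earlier gold
first); on small instances this matches the brute-force
overlap-maximizing assignment (tested exhaustively up to 4×4). Matched
pairs score 1 / 0.8 / 0.6 / 0.4 for exact / start-error / end-error /
both-errors; unmatched anything scores 0. Start errors cost less than end
errors: an annotation that begins late (e.g. swallowing the verb in
静滴恩度) still ends on the drug name and is clinically recoverable.
Matching is same-class only — a boundary-perfect prediction of the wrong
class scores 0. Precision divides summed scores by predicted-entity count,
recall by gold count (entity counts, not score sums, in the denominators);
percentages round to 0.1. Zero-overlap same-class adjacency counts as
unmatched. Soft-score distributions are summarized as (μ, σ); formal
significance testing between systems is out of scope.

## Synthetic corpus

The generator emulates the corpus structure the cascade assumes, with
defaults chosen to match the reference setting: medication-sentence rate
0.04, WM fraction of entities 0.732, train fraction 2/3, notes of 4–7
sections drawn from a 15-header inventory with 1–6 sentences each
(section-length distributions are arbitrary — the real ones are unknown —
and documented as such). Medication sentences instantiate
route/name/dose/frequency templates in three orders, with occasional
Latin aliases in parentheses and comma-enumerated second drugs; synthetic
TCM entities are 2–3-character herb names optionally extended by a form
suffix (丸/汤/颗粒…), WM entities are dictionary transliterations
optionally extended by 片/胶囊/注射液. Lab sections contain drug-like
blood-level lines (地高辛0.7ng/ml) that are *not* medication events,
exercising the section feature. Homophone typos are injected per
drug-name character at `typo_rate` using groups derived by inverting the
pinyin map; spans and transliterations are invariant by construction.
`held_out_fraction` removes names from both the emitted dictionaries and
the training split, so generalization to unseen drugs is measurable.
Compound abbreviations (维生素A、C) are generated separately as flagged
known-hard cases and excluded from headline scores. All randomness flows
from one `random.Random(seed)`.

What passing tests show: the cascade recovers entities whose contexts
follow the generator's templates, the ablation directions (full features ≥
local-context-only; filter on ≥ off; learned cascade > dictionary matching
under held-out drugs; pinyin channel > characters under typos) hold on
this distribution. What they do not show: performance on real clinical
notes, whose template diversity, abbreviation habits and annotation
ambiguities the generator does not model.

## Problem sizes and numerical defaults

Corpus-level tests use 300-note corpora (~4,300 sentences, ~190 medication
sentences) across five seeds — large enough for the binomial rates to
concentrate and for the filter's minority class to be learnable, small
enough to keep the whole suite in the minutes range. CRF: c2 = 0.1,
maxiter = 80, zero initialization; filter: alpha = 1e-4, max_iter = 1000,
tol = 1e-4, balanced class weights. Ranking and matching tiebreaks are
lexicographic / earlier-gold-first for determinism. Degenerate inputs are
contracts, not silent defaults: empty training sets, single-class filter
data, overlapping gold spans and BIO-invalid decode inputs all raise.

## Known limitations

One pinyin reading per character (no 多音字 disambiguation; 术 is read
`shu`); the default dictionaries are deliberately small; the CRF is
first-order with no semi-Markov spans, so very long entities lean on the
repair rules; general drug terms (抗生素 "antibiotics") and compound
abbreviations are expected misses; the filter is linear — its worked-vector
feature space is 6-dimensional by design, and no kernel or calibration is
provided.
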