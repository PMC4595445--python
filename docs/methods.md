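# Methods

## Problem and model

The package ranks candidate full-text articles by how *highly related* they
are to a target article — sharing the same research goal, methods and
findings, not merely overlapping vocabulary.  The signal is built from
out-link citations (the references an article cites), which are available
for any article the moment it is published, unlike in-links, which
accumulate slowly and are hard to collect completely.

Plain bibliographic coupling, `BC(d1,d2) = |O1 ∩ O2| / |O1 ∪ O2|` over the
resolved reference identities, fails precisely when two highly related
articles cite *different* papers about the same topic.  Passage-based
bibliographic coupling (PBC) repairs this by treating two references as
similar either when they are the same work, or when the citing authors
*commented* on them with similar words.  The commenting text of a reference
`c` in article `d` — its context passage `CP(c,d)` — is the set union of
the title tokens of `d` with, for each place `p` where `c` is cited, the
`α` tokens immediately preceding `p`.  Reference-pair similarity is 1 for
identical works and otherwise the Jaccard overlap of the two context
passages; it is weighted by the mean *importance* of the two references and
aggregated over both reference lists by best-match averaging (each
reference of either article is credited with its best counterpart in the
other, and the two sums are divided by `|O1| + |O2|`).  The score is
symmetric and lies in `[0, 2]`.

Assumptions worth stating: commenting text precedes the citation marker
(windows are taken *before* each mention only); a reference discussed at
least twice is more central to the citing article than one mentioned once;
and title tokens always belong to every reference's passage, which gives
every article pair a shared-title similarity floor under the text
component.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `α` | context-window length, in stopword-removed tokens before each mention | 10 (15 for the section-weighted variant) | about one sentence of commenting text; ranking quality is flat for α in 10–20 |
| importance strategy | frequency (2 if ≥ 2 mentions), position (`1 + max p/Length`), or section (2 in/after a "Result"-titled section) | frequency | the two alternatives are shipped as comparison variants |
| `k1`, `b` | BM25 saturation / length normalization in the text baseline | 8, 1.0 | the regime under which the BM25 product measure was tuned for article-to-article comparison |
| field view | title+abstract or whole article for the BM25 baseline | both available | key-part views are stronger for text measures; both are reported |
| stopword list | shipped `data/stopwords_en.txt`, one term per line, configurable | standard English IR list | metric values are mildly sensitive to the list, so it ships verbatim for reproducibility |

## Token normalization

Four rules in a fixed order: strip a trailing possessive `'s`; lowercase;
strip trailing `ing` when the remaining stem keeps ≥ 3 characters; strip one
trailing `s` unless the word ends in `ss`.  The order and the stem-length
guard were chosen so that "working"→"work", "works"→"work" hold while short
words ("ring", "king") are untouched.  Stopword membership is checked on
both the raw lowercased word and the normalized form, because the plural
rule maps surface stopwords like "was" to strings ("wa") no list contains.
Only unigrams are used.

## Conventions and degenerate inputs

- Mention positions are *insertion points* in the stopword-removed body
  stream (number of tokens before the marker), in `[0, Length]`; citation
  marker tokens themselves are excluded from the stream.  This makes the
  position weight of a final-token mention exactly 2 and makes the α-window
  `body[p-α : p]`.
- Grouped citation markers (`[3,4]`) give each member reference the same
  position.  Markers inside tables and figure captions do not count.
- A reference never cited in the body has a title-only passage and
  importance 1 under every strategy.
- Jaccard with an empty union is 0; an article with an empty reference list
  scores PBC = BC = 0 against everything (matching the convention that BC
  of two empty reference lists is 0).
- Citation identity resolves as PMID, else DOI, else a lowercase
  alphanumeric normalization of the citation string; unresolved references
  get a per-article sentinel so they enlarge Jaccard unions but never match.
- The text-only ablation applies the Jaccard term even to identical
  citations (the literal "lower branch"); the link-only ablation keeps the
  importance weighting, so it differs from plain BC by weighting and by
  best-match averaging rather than set intersection.
- Ranking ties break by ascending article id, so runs are deterministic.
  An optional pessimistic-ties mode charges a relevant item for every
  candidate scoring ≥ its own score when computing AP.
- Relevant articles absent from a ranking are appended after all scored
  candidates in ascending id order (they are effectively ranked last).
- Paired t-tests are made total: an all-zero difference vector reports
  p = 1 (no evidence of difference); a constant non-zero difference has
  zero variance and reports p = 0 with a `degenerate` flag instead of
  dividing by zero.  Degeneracy is detected with a small relative
  tolerance because metric differences are floating-point.

## Synthetic benchmark

The generator emulates the *shape* of an expert-curated gene–disease
retrieval benchmark: per topic, one target article, a small cluster of
highly related candidates, and a pool of near-miss candidates that share
only part of the topic vocabulary and none of its reference pool.  Two
parameters route the signal: `p_shared_reference` (probability a cluster
article's reference comes from the cluster's shared pool — feeds the link
signal) and `passage_overlap` (probability a context-window token comes
from the cluster vocabulary rather than an article-private one — feeds the
text signal).  Near-miss articles use half the passage-overlap rate and
titles drawn half from the cluster's title vocabulary, making them hard
negatives; their references are globally unique.  Candidate ids are
assigned through a seeded permutation so the deterministic id tie-break
carries no label information.  All randomness flows from one explicit seed;
generation is a pure function of the config.

Defaults are a desk-scale rendition of a 53-topic benchmark: 20 topics,
2 highly related candidates per target (the curated data this emulates
averages ~2.5), 12 near-misses per topic, ~10 references per article with
1–3 mentions each, and 10-token windows.  What the generator does **not**
emulate: real scientific prose (tokens are opaque symbols, so no
polysemy or morphology effects), realistic candidate-set sizes (real
topics have ~200 candidates, so absolute MAP values here are optimistic),
skewed reference-frequency distributions, or the expert selection process.
Passing tests therefore show that each measure recovers the *kind* of
structure it is designed for, not that real-corpus metric values are
reproduced.

## Evaluating recorded scores

The `s1-eval` pathway evaluates similarity values recorded by external
runs: a tab-separated table with key columns `topic_id, target_id,
candidate_id, highly_related` and one column per measure (the eight-measure
layout includes two externally computed hybrid columns whose formula this
package does not implement).  The loader is schema-driven and fails with
the detected headers rather than guessing; topics with no highly related
candidate are dropped with a warning.  This pathway is exercised end-to-end
in the tests by recording this package's own scores plus placeholder hybrid
columns and checking that the metrics recomputed from the table equal the
directly computed ones exactly.

## Verification

Every fast path is checked against an independent brute-force oracle:
context passages against a token-stream rescan; the article score against
full reference-pair enumeration (200 random small corpora, all variants);
average precision against the literal summation formula on every relevance
pattern of length ≤ 8; the link-only score against the closed-form Dice
coefficient when all importance weights are 1; and the BM25 scorer against
a hand-solved four-article fixture whose value is exactly 1.  Benchmark
properties (passage-regime: PBC beats BC; link-regime: PBC ≥ text-only)
hold across seeds.  `scripts/acceptance.py` re-derives all of these
quantities from scratch at a user-supplied seed.

## Known limitations

- Windows never extend *after* a citation marker, though commenting text
  occasionally follows it.
- Citation recognition requires numbered/hyperlinked markers (JATS `xref`
  elements); plain-text or PDF citation recognition is out of scope.
- The exact stopword list used by any external run is unknowable; shipped
  results are reproducible only relative to the bundled list.
- The α-window may cross sentence and paragraph boundaries, and does not
  skip the tokens of an immediately preceding citation cluster.
- Linguistic-pattern passage extraction and indirect/in-link coupling are
  deliberately not implemented.
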