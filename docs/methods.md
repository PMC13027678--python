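# Methods

This note documents the models and procedures `notestyle` implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical/design decisions that were genuinely open.

## Text normalization and segmentation

All analyses run on normalized text: Unicode NFKC, removal of a configurable
punctuation set (default: the common Japanese full-width marks 。、・「」『』（）
plus ASCII `.,;:!?()"'`), collapse of whitespace runs, strip. Punctuation is
*removed before* whitespace collapse so the result never contains double
spaces; the function is idempotent. Because the sentence delimiters (。, `.`,
newline) are themselves in the punctuation set, sentence segmentation runs on
the NFKC-normalized text *before* punctuation removal, and each sentence is
then normalized and tokenized. A consequence worth knowing: in unspaced text
(`a b。c d`) the whole-note token stream glues the characters around a removed
delimiter (`bc`), while the sentence view does not — for languages written
without spaces this is the intended behavior, and a morphological tokenizer
should be injected anyway.

Tokenization is a contract (`TokenizerSpec`): deterministic, whitespace-free
tokens. The default is whitespace splitting, which is correct for the
synthetic corpora and for pre-tokenized text; MeCab/Sudachi-style analyzers
can be injected for raw Japanese without touching any analysis code. Note
length defaults to tokens, with a character-count option, since the
appropriate unit is language- and tokenizer-dependent.

## Edit-distance engine and TER

The central primitive is a word-level Levenshtein dynamic program with unit
costs for insertion, deletion and substitution and *no* shift/reorder
operation. The DP table is filled row-by-row with numpy (the within-row
insertion recurrence is resolved by a min-plus prefix scan), and a backtrace
with a fixed tie-break — match/substitution preferred over deletion over
insertion — yields a canonical edit script. Conventions: the script transforms
the *hypothesis* into the *reference*; deleting a hypothesis token is a
deletion, inserting a reference token an insertion, so
`insertions − deletions = |ref| − |hyp|` identically.

TER is total edits divided by reference length (it may exceed 1). For the
pairwise matrix, both directions share one minimal distance D, so the
bidirectional average is D/2 · (1/|a| + 1/|b|) and each unordered pair is
solved once. Group edit summaries report mean per-operation counts normalized
by reference length, for both directions and symmetrized — the direction is
reported explicitly because "which text is the reference" reverses the
insertion/deletion roles, and with groups of very different note lengths the
asymmetry is the finding (the longer group as hypothesis shows deletions, the
reverse shows insertions).

## BLEU, ROUGE-L, embedding similarity

Sentence-level BLEU uses modified n-gram precisions up to order 4, a geometric
mean, and the standard brevity penalty; n-gram orders longer than either
sequence are skipped. Zero-count precisions are floored at ε = 0.1 counts by
default (`smoothing="epsilon"`); `"none"` returns 0. ROUGE-L is the LCS-based
F-measure with β = 1 (F1) by default; β weights recall. These defaults are
documented as this package's choices, not claims about any particular prior
analysis.

Embedding similarity implements the BERTScore contract — per-token vectors,
greedy max-cosine matching in both directions, F1, no baseline rescaling — as
an injection point. No pretrained model is bundled; a deterministic
hash-seeded backend (`HashEmbeddingBackend`) satisfies the contract offline
and is what the tests use. It carries no semantics: identical tokens match
perfectly, distinct tokens are near-orthogonal, so it behaves like exact token
overlap. Conclusions about *semantic* similarity require injecting a real
encoder.

## Similarity → distance, Ward clustering

TER is used directly as a distance; BLEU/ROUGE-L/embedding F1 are converted as
1 − score (recorded in the matrix metadata). For clustering, each note is
represented by its *distance profile* — its row of the pairwise matrix — and
Ward linkage runs on Euclidean distances between profiles. This is the
embedding a square distance matrix receives in the standard scipy/sklearn
workflow, and it is deliberately kept: with severely imbalanced groups (70
notes vs 4), Ward's size-weighted merge cost on raw pairwise distances makes
the last internal merges of a large diffuse cluster as expensive as merging
two small but distinct clusters, so a k-cluster cut can split the big group;
profile rows average each note's relation to the whole corpus and are much
more stable (group-recovery ARI ≥ 0.97 across 16 generator seeds at the
default study conditions, vs 0.67 worst-case for condensed-form linkage).
Dendrograms export as Newick and nested JSON; cuts use `fcluster(maxclust)`.

## TF-IDF group profiles

A single model is fitted on the combined corpus so all groups share vocabulary
and IDF weights — per-group fits would make scores incomparable. The default
weighting is the plain formula TF · log(N/DF) with raw counts, natural log
(configurable base) and no vector normalization: a term in every document
scores exactly 0, which makes "distinctive vocabulary" interpretable. The
scikit-learn variant (smoothed IDF, L2 rows) is available for comparability
with vectorizer-based analyses. Token filtering (rule-based multiword merging,
longest expression first, plus a stoplist) is user-supplied and empty by
default. Group profiles are per-term means over member documents, ranked with
lexicographic tie-breaks.

## Topic profiles

LDA via scikit-learn's batch variational inference, seeded and therefore
bit-reproducible. Defaults: K = 3, document-topic prior α = 1/K, topic-word
prior η = 0.01, 50 iterations; all configurable. Documents are bags of tokens
after the same token filter as the lexical module, for consistency. Group
profiles are arithmetic means of member documents' topic proportions — this is
the group-size normalization: a 4-note group and a 70-note group are compared
on the same simplex. Topic identity is not stable across refits with different
seeds (label switching); tests match topics to planted structure by dominant
mass before asserting.

## Term-variation entropy

Surface forms of a concept are counted in each group's normalized text by
exact substring matching with longest-form priority at each position,
advancing past a match (so "depressive state" is one hit, not also a
"depressive" hit). Counts pool all notes in a group by default (one entropy
per group); a per-note presence option exists. Entropy is Shannon entropy in
bits with 0·log 0 = 0; it is 0 when one form carries all mass and log₂ n at
uniformity over n observed forms. The dictionary is user-supplied (TSV or
JSON); no licensed lexicon is bundled.

## Redundancy metrics

Per note: sentence count (periods/line breaks); TTR; inter-sentence
redundancy = mean pairwise cosine similarity between TF-IDF sentence vectors
(equivalently 1 − mean cosine distance), defined as 0 for single-sentence
notes; DEFLATE (zlib level 6, configurable) compressed/original byte ratio of
the normalized UTF-8 text; mean per-sentence unique-token count (a
whole-note-unique/sentence-count alternative is behind a flag); and
1 − unique/total adjacent bigrams (0 below 2 tokens). The sentence vectorizer
is note-local with smoothed IDF and L2 normalization, so a term present in
every sentence keeps a nonzero weight and identical sentences score exactly 1.
Compression ratios are compressor- and level-dependent; compare them only at a
fixed level, and tests assert only the monotone contrast (repetitive text
compresses further), never absolute values.

## Statistical layer

Two-sided tests throughout. The t test defaults to Welch; a pooled-variance
option exists (pooled df for n=4 vs n=4 is 6). Mann-Whitney U uses the exact
null distribution when min(n, m) ≤ 8 and there are no ties, otherwise the
normal approximation with tie correction. Cliff delta is computed by direct
pair counting. FDR correction is Benjamini-Hochberg step-up (via statsmodels);
note the step-up adjustment is order-equivariant and monotone but *not*
idempotent — re-adjusting adjusted values changes them, which is a property of
the procedure, not a bug.

The downsampling sensitivity analysis targets the group-size imbalance
question: could a small group's extreme metric value be a small-sample
artifact? The large reference group is resampled *without replacement* to the
small group's size B times (subsampling, which is what "downsampling to match
the sample size" means; a with-replacement bootstrap is behind a flag), the
resample mean (or median) forms an empirical distribution, and the observed
value is flagged if outside the 2.5–97.5 percentile range. Monte-Carlo
calibration: with reference and observed drawn from one distribution
(n_target = 4, B = 1000, 500 replicates) the flag fires at ~5–7%, consistent
with the nominal 5% once the reference-sample noise is accounted for. All
resampling is seeded and bit-reproducible.

## Synthetic-data generator

The generator produces the style contrasts the pipeline is meant to detect,
with per-group `StyleParams`:

- **Lengths** from a truncated normal (floor 5 tokens). Default study: means
  70 (psychiatrist-like), 45 (internist-like), 210 and 120 (LLM-like, ~3×),
  with relative SD harmonized at ~12–13% of the mean for every group — TER
  divides by reference length, so a group with unusually large *relative*
  length spread acquires bimodal distance profiles purely as a ratio artifact.
- **Template skeletons.** Each group has an ordered pool of template sentences
  (clinical notes follow a canonical section order); body sentence i is the
  verbatim (i mod pool)-th template with probability `template_reuse_p`
  (humans 0.8, pool 6; LLM-like 0.9, pool 3), else freshly sampled from the
  group vocabulary. Ordered reuse is what creates alignable within-group
  structure; unordered draws leave almost no common subsequence.
- **Sentence repetition** duplicates the previous sentence with probability
  0.02 (human-like) / 0.25 (LLM-like).
- **Vocabularies** are contiguous, partially overlapping blocks of a shared
  synthetic lexicon (`w0412`-style tokens): sizes 400/300 for human-like
  groups with 50% overlap, 120 for each LLM-like group, disjoint between LLM
  styles. Small vocabulary plus heavy reuse yields the low TTR and high bigram
  duplication of LLM-like text.
- **Sentence lengths** 6–12 tokens for human-like groups, 4–8 (bullet-like
  template lines) for LLM-like groups — the mechanism behind the lower
  unique-words-per-sentence of templated notes.
- **Concept variants**: per note, 1 + Poisson(1.5) mentions of the
  "depressive state" concept are drawn from the group's surface-form
  distribution and embedded contiguously inside body sentences. Configured
  entropies: psychiatrist-like 3.0 bits (8 uniform forms), LLM-psychiatry-like
  ≈ 2.47, LLM-internal-like ≈ 1.85, internist-like ≈ 1.35 — the diversity
  ordering observed between flexible and formulaic documentation styles.
- Each group also carries two **marker tokens** injected into its templates
  (distinctive vocabulary for the TF-IDF profile), and LLM-like notes cycle
  through four synthetic model names.

Group sizes default to 70/48/4/4. Generation is bit-reproducible from the
`SyntheticTruth` (parameters + seed), which serializes to JSON next to the
corpus.

**What the generator does not emulate** — and hence what passing tests do and
do not show: tokens are synthetic symbols, so nothing is claimed about real
tokenizers, morphology or semantics; style dimensions are independent knobs,
whereas real authorship correlates them; there is no scenario/content
structure beyond a case-id label, no discourse coherence, and no model-specific
idiosyncrasies. End-to-end tests demonstrate that the *pipeline* detects the
configured contrasts at realistic sizes and imbalance — they are not evidence
about any particular clinical corpus.

## Numerical choices and degenerate inputs

Empty reference → TER undefined (error); empty sequences → BLEU/ROUGE/embedding
errors naming the offending pair; empty note → redundancy error; zero variant
occurrences → entropy error (NaN in the batch table); all-identical pooled
values → degenerate-variance error for parametric tests; single group →
between-group pipeline stages are skipped with explicit manifest notices.
Ranking ties (TF-IDF terms, topic words) break lexicographically. Ward merge
ties follow scipy's deterministic lowest-index order. Floating-point
comparisons in tests use closed-form values with explicit tolerances.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the full default study corpus
(126 notes, ~11k tokens), 200 random pairs for the edit-distance oracle, 500
Monte-Carlo replicates × B = 1000 for bootstrap calibration, and 40 documents
for planted-topic recovery — sizes at which every check completes in seconds
on one CPU while the statistics (ARI, calibration rate) are stable.

## Known limitations

- TER here excludes shift operations by design; texts differing mainly by
  block reordering are scored as far apart.
- The embedding-similarity stage is only as meaningful as the injected
  backend; the bundled hash backend is a determinism/contract device.
- The paper-formula TF-IDF assigns 0 to ubiquitous terms, which is intended
  for *distinctiveness* ranking but unsuitable as a general-purpose document
  representation.
- Compression-ratio values are not comparable across zlib levels or
  implementations.
- LDA results depend on K and the priors; no model-selection machinery is
  included.
- Variant matching is exact substring matching on normalized text; it does not
  handle inflection or spelling variants not listed in the dictionary.
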