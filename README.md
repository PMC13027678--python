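# notestyle

Quantitative, multi-axis comparison of clinical-note documentation *styles*
across author groups — for example psychiatrists vs internists vs large
language models prompted to write in each specialty's style.

Clinical NLP researchers and documentation-quality groups often need to answer
questions like: do LLM-drafted notes look like the notes physicians actually
write? Are they longer, more repetitive, more template-like? Do specialties
retain their distinctive vocabulary and thematic emphasis? `notestyle`
implements a reusable pipeline for exactly this kind of stylometric
comparison, together with a seeded synthetic-corpus generator that emulates
the relevant style contrasts so every analysis is testable end to end without
access to (usually non-shareable) clinical text.

## What it computes

**Structural similarity and clustering.** For every note pair, the translation
edit rate

&nbsp;&nbsp;&nbsp;&nbsp;TER = (number of edits) / (number of words in the reference),

where the minimal word-level edit script uses insertions, deletions and
substitutions (no shift operation), is computed by an exact dynamic program
with a canonical backtrace, alongside BLEU, ROUGE-L (LCS-based F-measure) and
a pluggable token-embedding similarity (greedy max-cosine matching, F1, the
BERTScore contract). Directional scores are averaged in both directions into a
symmetric matrix; Ward hierarchical clustering on the distance matrix yields a
dendrogram (Newick/JSON export) and flat style clusters. Per-group-pair means
of insertions/deletions/substitutions, normalized by reference length, expose
*why* groups differ (e.g. longer notes show up as deletions when the shorter
group is the reference).

**Lexical profile.** One TF-IDF model, TF-IDF(t,d) = TF(t,d) · log N/DF(t), is
fitted over the combined corpus so vocabulary and IDF weights are shared, then
per-group mean term scores rank each group's distinctive vocabulary. Both the
plain formula above and the scikit-learn smoothed/L2 variant are available.

**Topic profile.** Latent Dirichlet allocation (K = 3 by default) over all
notes; group profiles are means of member documents' topic proportions, which
normalizes for group size.

**Term variation.** Given a concept → surface-forms dictionary, occurrences of
each form are counted per group (exact match on normalized text, longest form
first) and expression diversity is summarized as Shannon entropy
H = −Σ pᵢ log₂ pᵢ in bits.

**Redundancy.** Six per-note metrics: sentence count, type-token ratio,
inter-sentence TF-IDF cosine similarity, DEFLATE compression ratio, unique
words per sentence, and adjacent-bigram duplication rate — plus per-group
aggregates.

**Statistics.** Length descriptives, one-way ANOVA, Welch/pooled t tests,
Mann-Whitney U (exact null for small tie-free samples), Cliff delta effect
sizes, Benjamini-Hochberg FDR correction, and a bootstrap *downsampling*
sensitivity analysis that asks whether a small group's observed value lies
outside the 95% range of statistics from repeated size-matched subsamples of a
large group.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from notestyle import (default_study_truth, default_variant_dictionary,
                       generate_corpus, group_entropy_table, group_redundancy,
                       length_test_table, pairwise_matrix, ward_cluster)

corpus = generate_corpus(default_study_truth(seed=1))
# {'psychiatry_human': 70, 'internal_medicine_human': 48,
#  'psychiatry_llm': 4, 'internal_medicine_llm': 4}

length_test_table(corpus)[["test", "groups", "statistic", "p", "effect_size"]]
#               anova_oneway   all                               332.44  1.6e-58
#  mann_whitney_u[asymptotic]  psychiatry_human vs internal_...  3347.0  6.6e-20  0.99
#  mann_whitney_u[asymptotic]  psychiatry_human vs psychiatry_llm   0.0  8.4e-04 -1.00

mat = pairwise_matrix(corpus, "ter")
clusterer, labels = ward_cluster(mat, k=4)
adjusted_rand_score(corpus.labels(), labels)          # 0.998

group_redundancy(corpus).pivot(index="group", columns="metric", values="mean")
#                            ttr  bigram_duplication
# internal_medicine_human  0.857               0.025
# internal_medicine_llm    0.262               0.642
# psychiatry_human         0.814               0.073
# psychiatry_llm           0.166               0.773

group_entropy_table(corpus, default_variant_dictionary(), "depressive state")
#                    group  entropy_bits
#         psychiatry_human         2.981
#  internal_medicine_human         1.351
#           psychiatry_llm         2.000
#    internal_medicine_llm         1.842
```

Reading the output: the four synthetic author groups separate almost perfectly
under TER-based Ward clustering (adjusted Rand index 0.998 against the true
groups); the LLM-like groups are far longer (Cliff δ = −1.0 means every
psychiatrist note is shorter than every LLM note), lexically poorer (TTR 0.17
vs 0.81) and much more repetitive (bigram duplication 0.77 vs 0.07); and the
psychiatrist-like group expresses the "depressive state" concept with the most
varied surface forms (3.0 bits vs 1.4 for the internist-like group).

The same pipeline runs from the shell:

```bash
notestyle simulate --seed 1 --out corpus.jsonl
notestyle analyze --corpus corpus.jsonl --out results \
    --dictionary corpus.variants.json
notestyle report --manifest results/manifest.json
```

`analyze` writes every table as CSV/JSON plus a manifest with the config hash
and seeds; `report` renders a readable summary.

## Layout

| module | contents |
| --- | --- |
| `notestyle.corpus` | `Note`/`GroupedCorpus`, normalization, segmentation, pluggable tokenizers, JSONL + manifest I/O |
| `notestyle.similarity` | TER/edit ops, BLEU, ROUGE-L, embedding F1, pairwise matrices, `WardClusterer`, group edit summaries |
| `notestyle.lexical` | `GroupTfidfProfiler` (shared-vocabulary TF-IDF, group keyword profiles) |
| `notestyle.topics` | `GroupTopicModel` (seeded LDA, group topic means, top words) |
| `notestyle.variation` | variant dictionaries, form counting, lexical entropy |
| `notestyle.redundancy` | `RedundancyProfiler` (six-metric profile) and group aggregates |
| `notestyle.stats` | tests, effect sizes, FDR, bootstrap downsampling |
| `notestyle.simulate` | `StyleParams`/`SyntheticTruth` and the seeded corpus generator |
| `notestyle.pipeline` / `notestyle.cli` | end-to-end analysis, manifest, report, console script |

See `docs/methods.md` for the modelling choices, parameter defaults and known
limitations.
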