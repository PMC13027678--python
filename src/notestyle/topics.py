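"""LDA topic modeling over all notes and group-size-normalized topic profiles.

Documents (bags of tokens, after the same token filter as the lexical module)
are modeled with latent Dirichlet allocation; each group's thematic profile is
the arithmetic mean of its member documents' topic-proportion vectors, which
normalizes for group size so small and large author groups are comparable.

Inference is scikit-learn's batch variational LDA with a fixed seed, so fits
are bit-reproducible.  Defaults: K = 3 topics, doc-topic prior alpha = 1/K,
topic-word prior eta = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

from .corpus import GroupedCorpus
from .lexical import TokenFilter

__all__ = ["GroupTopicModel", "TopicModelResult", "fit_topics",
           "group_topic_means", "topic_top_words"]


@dataclass
class TopicModelResult:
    """Fitted topic-model summary: per-document topic proportions and
    per-topic word distributions (all rows on the simplex)."""

    n_topics: int
    doc_topic: np.ndarray
    topic_word: np.ndarray
    terms: np.ndarray
    seed: int
    alpha: float
    eta: float
    inference: str = "variational_batch"


class GroupTopicModel(BaseEstimator):
    """scikit-learn-style LDA wrapper producing group topic profiles.

    Fitted attributes: ``doc_topic_`` (n_docs, K; rows sum to 1),
    ``topic_word_`` (K, vocab; rows sum to 1), ``terms_``, ``result_``.
    """

    def __init__(self, n_topics: int = 3, seed: int = 0,
                 alpha: float | None = None, eta: float = 0.01,
                 token_filter: TokenFilter = TokenFilter(),
                 max_iter: int = 50):
        self.n_topics = n_topics
        self.seed = seed
        self.alpha = alpha
        self.eta = eta
        self.token_filter = token_filter
        self.max_iter = max_iter

    def fit(self, corpus: GroupedCorpus, y=None) -> "GroupTopicModel":
        if self.n_topics < 2:
            raise ValueError("n_topics must be >= 2")
        if len(corpus) < self.n_topics:
            raise ValueError("corpus must have at least n_topics documents")
        docs = [self.token_filter(n.tokens) for n in corpus.notes]
        if all(len(d) == 0 for d in docs):
            raise ValueError("degenerate corpus: all documents are empty")
        vectorizer = CountVectorizer(analyzer=lambda d: d, lowercase=False)
        counts = vectorizer.fit_transform(docs)
        alpha = self.alpha if self.alpha is not None else 1.0 / self.n_topics
        lda = LatentDirichletAllocation(
            n_components=self.n_topics,
            doc_topic_prior=alpha,
            topic_word_prior=self.eta,
            learning_method="batch",
            max_iter=self.max_iter,
            random_state=self.seed,
        )
        doc_topic = lda.fit_transform(counts)
        self.doc_topic_ = doc_topic / doc_topic.sum(axis=1, keepdims=True)
        self.topic_word_ = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
        self.terms_ = vectorizer.get_feature_names_out()
        self.note_ids_ = corpus.note_ids
        self.result_ = TopicModelResult(
            n_topics=self.n_topics, doc_topic=self.doc_topic_,
            topic_word=self.topic_word_, terms=self.terms_,
            seed=self.seed, alpha=alpha, eta=self.eta)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "doc_topic_"):
            raise RuntimeError("GroupTopicModel is not fitted")

    def group_means(self, corpus: GroupedCorpus) -> pd.DataFrame:
        """Group x topic table of mean member topic proportions (rows sum to 1)."""
        self._check_fitted()
        if corpus.note_ids != self.note_ids_:
            raise ValueError("model was fitted on a different corpus")
        labels = np.asarray(corpus.labels())
        rows, index = [], []
        for g in corpus.group_labels:
            mask = labels == g
            if not mask.any():
                raise ValueError(f"group {g!r} has zero documents")
            rows.append(self.doc_topic_[mask].mean(axis=0))
            index.append(g)
        return pd.DataFrame(
            rows, index=index,
            columns=[f"topic_{k}" for k in range(self.n_topics)])

    def top_words(self, topic: int, k: int = 10) -> list[tuple[str, float]]:
        """k highest-probability words of one topic (ties lexicographic)."""
        self._check_fitted()
        if not 0 <= topic < self.n_topics:
            raise ValueError(f"topic index {topic} out of range [0, {self.n_topics})")
        probs = self.topic_word_[topic]
        order = sorted(zip(self.terms_, probs), key=lambda kv: (-kv[1], kv[0]))
        return [(t, float(p)) for t, p in order[:min(k, len(order))]]


def fit_topics(corpus: GroupedCorpus, K: int = 3, seed: int = 0,
               alpha: float | None = None, eta: float = 0.01,
               token_filter: TokenFilter = TokenFilter()) -> GroupTopicModel:
    return GroupTopicModel(n_topics=K, seed=seed, alpha=alpha, eta=eta,
                           token_filter=token_filter).fit(corpus)


def group_topic_means(model: GroupTopicModel, corpus: GroupedCorpus) -> pd.DataFrame:
    return model.group_means(corpus)


def topic_top_words(model: GroupTopicModel, topic: int, k: int = 10):
    return model.top_words(topic, k)
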