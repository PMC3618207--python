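"""Latent Dirichlet Allocation over PICO-only text.

The topic model is fitted on the PICO portions of the training protocols
and later used to infer per-document topic proportions, both for the
pseudo-label partitions of anchored training and for the sample set a
user supplies at scoring time.

Fitting is delegated to scikit-learn's variational-Bayes LDA.  Variational
posteriors are smoothed by the document-topic prior and therefore never
exactly zero, which would leave the negative pseudo-label pool (topic
proportion <= kappa2 with kappa2 = 0) empty.  We therefore report
count-style proportions: the prior is subtracted from the variational
pseudo-counts, entries below a small floor are snapped to exactly zero,
and the row is renormalized.  A topic to which a document effectively
assigns no tokens then has proportion exactly 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.special import psi
from sklearn.decomposition import LatentDirichletAllocation

from .corpus_io import Vocabulary

logger = logging.getLogger(__name__)

#: smoothed proportions below this are treated as exactly zero
ZERO_PROPORTION_TOL = 1e-4


@dataclass(frozen=True)
class TopicModelParams:
    """Hyperparameters of the n-topic model.

    alpha is the document-topic concentration (defaults to 1/n when left
    unset, the variational-Bayes convention; a sparse prior also keeps the
    count-style proportions sparse), beta the topic-word concentration,
    iterations the number of variational EM passes.
    """

    n: int
    alpha: float | None = None
    beta: float = 0.01
    iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one topic")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def effective_alpha(self) -> float:
        return 1.0 / self.n if self.alpha is None else self.alpha


@dataclass
class TopicProportionMatrix:
    """Per-document topic weights; each row is a probability vector."""

    doc_ids: list[str]
    weights: np.ndarray  # shape (m, n)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != len(self.doc_ids):
            raise ValueError("weights shape does not match doc_ids")
        if (self.weights < 0).any():
            raise ValueError("topic proportions must be non-negative")
        sums = self.weights.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("topic proportion rows must sum to 1")

    @property
    def n_topics(self) -> int:
        return self.weights.shape[1]

    def row(self, doc_id: str) -> np.ndarray:
        return self.weights[self.doc_ids.index(doc_id)]


@dataclass
class FittedTopicModel:
    params: TopicModelParams
    vocab: Vocabulary
    components: np.ndarray = field(repr=False)  # variational lambda, (n, V)
    corpus_fingerprint: str = ""

    @property
    def n_topics(self) -> int:
        return self.params.n

    @property
    def topic_word(self) -> np.ndarray:
        """Row-normalized per-topic word distributions."""
        return self.components / self.components.sum(axis=1, keepdims=True)

    # -- serialization (plain JSON; floats round-trip via repr) ------------
    def to_json(self) -> str:
        return json.dumps({
            "schema": "ldalr-topic-model/1",
            "params": {"n": self.params.n, "alpha": self.params.alpha,
                       "beta": self.params.beta,
                       "iterations": self.params.iterations,
                       "seed": self.params.seed},
            "vocab": self.vocab.index_to_token,
            "components": self.components.tolist(),
            "corpus_fingerprint": self.corpus_fingerprint,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FittedTopicModel":
        d = json.loads(text)
        return cls(params=TopicModelParams(**d["params"]),
                   vocab=Vocabulary(d["vocab"]),
                   components=np.asarray(d["components"], dtype=float),
                   corpus_fingerprint=d.get("corpus_fingerprint", ""))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "FittedTopicModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _doc_term_matrix(token_lists: Sequence[Sequence[str]], vocab: Vocabulary
                     ) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    for r, toks in enumerate(token_lists):
        counts: dict[int, int] = {}
        for t in toks:
            j = vocab.token_to_index.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j in sorted(counts):
            rows.append(r)
            cols.append(j)
            vals.append(counts[j])
    return sparse.csr_matrix((vals, (rows, cols)),
                             shape=(len(token_lists), len(vocab)), dtype=float)


def _sklearn_lda(params: TopicModelParams) -> LatentDirichletAllocation:
    return LatentDirichletAllocation(
        n_components=params.n,
        doc_topic_prior=params.effective_alpha,
        topic_word_prior=params.beta,
        max_iter=params.iterations,
        learning_method="batch",
        evaluate_every=-1,
        random_state=params.seed,
        n_jobs=1,
    )


def fit_topic_model(pico_token_lists: Sequence[Sequence[str]],
                    params: TopicModelParams) -> FittedTopicModel:
    """Fit the n-topic model on per-document PICO token lists.

    Documents with no tokens are dropped (with a warning) before fitting;
    deterministic under a fixed seed.
    """
    nonempty = [t for t in pico_token_lists if len(t) > 0]
    n_dropped = len(pico_token_lists) - len(nonempty)
    if n_dropped:
        logger.warning("dropping %d empty documents before topic fitting",
                       n_dropped)
    if not nonempty:
        raise ValueError("all documents are empty; cannot fit a topic model")
    vocab = Vocabulary([t for toks in nonempty for t in toks])
    if params.n > len(vocab):
        raise ValueError(
            f"number of topics ({params.n}) exceeds vocabulary size "
            f"({len(vocab)})")
    X = _doc_term_matrix(nonempty, vocab)
    lda = _sklearn_lda(params).fit(X)

    import hashlib
    fp = hashlib.sha256(
        json.dumps([sorted(t) for t in nonempty]).encode()).hexdigest()[:16]
    return FittedTopicModel(params=params, vocab=vocab,
                            components=lda.components_, corpus_fingerprint=fp)


def _transform_model(model: FittedTopicModel) -> LatentDirichletAllocation:
    """Rebuild a transform-capable sklearn LDA from stored components."""
    lda = _sklearn_lda(model.params)
    comp = np.asarray(model.components, dtype=float)
    lda.components_ = comp
    lda.exp_dirichlet_component_ = np.exp(
        psi(comp) - psi(comp.sum(axis=1))[:, None])
    lda.n_features_in_ = comp.shape[1]
    lda.doc_topic_prior_ = model.params.effective_alpha
    lda.topic_word_prior_ = model.params.beta
    lda.n_iter_ = 0
    lda.bound_ = np.nan
    lda.random_state_ = np.random.RandomState(model.params.seed)
    return lda


def infer_proportions(model: FittedTopicModel,
                      docs: Sequence[Sequence[str]],
                      doc_ids: Sequence[str] | None = None,
                      zero_tol: float = ZERO_PROPORTION_TOL
                      ) -> TopicProportionMatrix:
    """Infer count-style topic proportions for tokenized documents.

    Out-of-vocabulary tokens are ignored.  A document with no in-vocabulary
    tokens receives the uniform row 1/n (with a warning).  The document-topic
    prior is subtracted from the variational pseudo-counts and entries below
    ``zero_tol`` (after normalization) are snapped to exactly 0, so that
    "document has none of this topic" is representable.
    """
    if doc_ids is None:
        doc_ids = [str(i) for i in range(len(docs))]
    n = model.n_topics
    X = _doc_term_matrix(docs, model.vocab)
    lengths = np.asarray(X.sum(axis=1)).ravel()
    W = np.full((len(docs), n), 1.0 / n)
    nonempty = lengths > 0
    if (~nonempty).any():
        logger.warning(
            "%d document(s) have no in-vocabulary tokens; using uniform "
            "topic proportions", int((~nonempty).sum()))
    if nonempty.any():
        lda = _transform_model(model)
        gamma_norm = lda.transform(X[nonempty])
        alpha = model.params.effective_alpha
        gamma = gamma_norm * (lengths[nonempty] + n * alpha)[:, None]
        counts = np.clip(gamma - alpha, 0.0, None)
        # empty posterior mass (should not happen for nonempty docs) -> uniform
        zero_rows = counts.sum(axis=1) <= 0
        counts[zero_rows] = 1.0
        props = counts / counts.sum(axis=1, keepdims=True)
        props[props < zero_tol] = 0.0
        props /= props.sum(axis=1, keepdims=True)
        W[nonempty] = props
    return TopicProportionMatrix(doc_ids=list(doc_ids), weights=W)


def top_words(model: FittedTopicModel, topic: int, k: int) -> list[str]:
    """The k most probable tokens of one topic, ties broken lexicographically."""
    if not 0 <= topic < model.n_topics:
        raise IndexError(f"topic {topic} out of range [0, {model.n_topics})")
    if k < 1:
        raise ValueError("k must be >= 1")
    row = model.topic_word[topic]
    order = sorted(range(len(row)),
                   key=lambda j: (-row[j], model.vocab.index_to_token[j]))
    return [model.vocab.index_to_token[j] for j in order[:k]]
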