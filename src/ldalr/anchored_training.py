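"""Anchored training: per-topic classifiers from topic pseudo-labels.

For each latent topic i the training corpus is split into a positive pool
L_i (documents whose topic-i proportion exceeds kappa1) and a negative
pool L_-i (proportion at most kappa2).  Every eligibility criterion of
the requested kind in a pooled document becomes one labeled training
instance, featurized as the union of its own tokens and the PICO tokens
of its source document.  An L2-regularized logistic regression is then
fitted per topic, one set for inclusion criteria and one for exclusion.

The pseudo-labels are noisy by construction — a positive document merely
has *some* of topic i in its mixture — but carry enough signal for the
classifiers to beat chance, which is all the downstream expected-value
scoring needs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .corpus_io import (Criterion, CriterionKind, FeatureVector,
                        ProtocolDocument, Vocabulary, featurize)
from .topic_model import TopicProportionMatrix

logger = logging.getLogger(__name__)


class UntrainableTopicError(ValueError):
    """Raised when a topic has an empty positive or negative pseudo-label pool."""


@dataclass(frozen=True)
class AnchorConfig:
    """Thresholds and training settings for anchored training.

    kappa1/kappa2 are in topic-proportion units; a document is a positive
    example of topic i when w_i > kappa1 and a negative when w_i <= kappa2.
    neg_cap bounds the negative pool at neg_cap * |positives| (0 disables).
    """

    kappa1: float = 0.02
    kappa2: float = 0.0
    regularization: float = 1.0   # inverse strength C of the L2 penalty
    folds: int = 10
    balance: bool = False
    neg_cap: int = 5
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.kappa2 < self.kappa1 <= 1:
            raise ValueError("need 0 <= kappa2 < kappa1 <= 1")
        if self.regularization <= 0:
            raise ValueError("regularization strength must be positive")


@dataclass
class PseudoLabelPartition:
    topic: int
    positives: list[str]   # document ids in L_i
    negatives: list[str]   # document ids in L_-i


@dataclass
class TopicClassifier:
    """Probability model p_i for one topic: P(T(s) = i | features).

    A plain weight-vector + intercept logistic model; ``constant`` replaces
    the linear model for degenerate (untrainable) topics.  The probability
    is computed with a sequential left-to-right accumulation over sorted
    feature indices, which makes scores exactly reproducible.
    """

    topic: int
    kind: CriterionKind
    coef: np.ndarray | None = field(default=None, repr=False)
    intercept: float = 0.0
    constant: float | None = None

    def predict_prob(self, features: FeatureVector) -> float:
        if self.constant is not None:
            return self.constant
        z = self.intercept
        for j in sorted(features):
            z += self.coef[j]
        if z >= 0:
            return 1.0 / (1.0 + math.exp(-z))
        ez = math.exp(z)
        return ez / (1.0 + ez)


@dataclass
class ClassifierSet:
    """The n per-topic classifiers of one criterion kind, index-aligned."""

    kind: CriterionKind
    classifiers: list[TopicClassifier]
    vocab: Vocabulary
    feature_mode: str = "criterion+pico"
    degenerate_topics: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.classifiers)

    def to_json(self) -> str:
        return json.dumps({
            "schema": "ldalr-classifiers/1",
            "kind": self.kind,
            "feature_mode": self.feature_mode,
            "vocab": self.vocab.index_to_token,
            "degenerate_topics": self.degenerate_topics,
            "classifiers": [
                {"topic": c.topic, "constant": c.constant,
                 "intercept": c.intercept,
                 "coef": None if c.coef is None else c.coef.tolist()}
                for c in self.classifiers],
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierSet":
        d = json.loads(text)
        clfs = [TopicClassifier(
            topic=c["topic"], kind=d["kind"],
            coef=None if c["coef"] is None else np.asarray(c["coef"]),
            intercept=c["intercept"], constant=c["constant"])
            for c in d["classifiers"]]
        return cls(kind=d["kind"], classifiers=clfs,
                   vocab=Vocabulary(d["vocab"]),
                   feature_mode=d["feature_mode"],
                   degenerate_topics=d.get("degenerate_topics", []))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierSet":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def features_to_csr(feature_sets: Sequence[FeatureVector], n_features: int
                    ) -> sparse.csr_matrix:
    rows, cols = [], []
    for r, fs in enumerate(feature_sets):
        for j in sorted(fs):
            rows.append(r)
            cols.append(j)
    data = np.ones(len(rows))
    return sparse.csr_matrix((data, (rows, cols)),
                             shape=(len(feature_sets), n_features))


def partition_by_topic(W: TopicProportionMatrix, i: int, cfg: AnchorConfig
                       ) -> PseudoLabelPartition:
    """Positive pool w_i > kappa1, negative pool w_i <= kappa2, gap excluded."""
    if not 0 <= i < W.n_topics:
        raise IndexError(f"topic {i} out of range")
    col = W.weights[:, i]
    positives = [W.doc_ids[d] for d in range(len(col)) if col[d] > cfg.kappa1]
    negatives = [W.doc_ids[d] for d in range(len(col)) if col[d] <= cfg.kappa2]
    if not positives or not negatives:
        raise UntrainableTopicError(
            f"topic {i}: {len(positives)} positives / {len(negatives)} "
            f"negatives; classifier untrainable")
    return PseudoLabelPartition(topic=i, positives=positives,
                                negatives=negatives)


def make_training_instances(partition: PseudoLabelPartition,
                            kind: CriterionKind,
                            corpus: dict[str, ProtocolDocument],
                            vocab: Vocabulary,
                            feature_mode: str = "criterion+pico",
                            ) -> tuple[list[FeatureVector], np.ndarray]:
    """One labeled instance per criterion of ``kind`` per pooled document."""
    X: list[FeatureVector] = []
    y: list[int] = []
    for doc_ids, label in ((partition.positives, 1), (partition.negatives, -1)):
        for doc_id in doc_ids:
            doc = corpus[doc_id]
            for crit in doc.criteria(kind):
                X.append(featurize(crit, doc, vocab, mode=feature_mode))
                y.append(label)
    return X, np.asarray(y)


def train_topic_classifier(X: Sequence[FeatureVector], y: np.ndarray,
                           cfg: AnchorConfig, vocab_size: int,
                           topic: int = 0, kind: CriterionKind = "inclusion"
                           ) -> TopicClassifier:
    """L2-regularized logistic regression on binary feature sets."""
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise UntrainableTopicError(
            f"topic {topic}: single-class training data")
    M = features_to_csr(X, vocab_size)
    lr = LogisticRegression(C=cfg.regularization, solver="liblinear",
                            tol=cfg.tol, random_state=0)  # L2 penalty default
    lr.fit(M, y)
    coef = lr.coef_.ravel().copy()
    intercept = float(lr.intercept_[0])
    if lr.classes_[1] != 1:   # ensure probabilities refer to the +1 class
        coef, intercept = -coef, -intercept
    return TopicClassifier(topic=topic, kind=kind, coef=coef,
                           intercept=intercept)


def anchor_train(corpus: Sequence[ProtocolDocument], W: TopicProportionMatrix,
                 cfg: AnchorConfig, kind: CriterionKind, vocab: Vocabulary,
                 feature_mode: str = "criterion+pico") -> ClassifierSet:
    """Train one classifier per topic from topic pseudo-labels.

    Topics whose pseudo-label partition cannot support training degrade to
    the constant-0.5 predictor (recorded in ``degenerate_topics``) so that
    downstream scoring never crashes; an error is raised only when *every*
    topic is untrainable.
    """
    by_id = {d.id: d for d in corpus}
    missing = [i for i in W.doc_ids if i not in by_id]
    if missing:
        raise ValueError(f"proportion matrix covers unknown documents: "
                         f"{missing[:3]}...")
    classifiers: list[TopicClassifier] = []
    degenerate: list[int] = []
    for i in range(W.n_topics):
        try:
            part = partition_by_topic(W, i, cfg)
            if cfg.neg_cap and len(part.negatives) > cfg.neg_cap * len(part.positives):
                cap = cfg.neg_cap * len(part.positives)
                rng = np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, i]))
                keep = rng.choice(len(part.negatives), size=cap, replace=False)
                part.negatives = [part.negatives[j] for j in sorted(keep)]
                logger.info("topic %d: negative pool capped at %d", i, cap)
            X, y = make_training_instances(part, kind, by_id, vocab,
                                           feature_mode)
            clf = train_topic_classifier(X, y, cfg, len(vocab),
                                         topic=i, kind=kind)
        except UntrainableTopicError as exc:
            logger.warning("topic %d degraded to constant predictor (%s)",
                           i, exc)
            clf = TopicClassifier(topic=i, kind=kind, constant=0.5)
            degenerate.append(i)
        classifiers.append(clf)
    if len(degenerate) == W.n_topics:
        raise UntrainableTopicError("every topic is untrainable")
    return ClassifierSet(kind=kind, classifiers=classifiers, vocab=vocab,
                         feature_mode=feature_mode,
                         degenerate_topics=degenerate)


def cross_validate(X: Sequence[FeatureVector], y: np.ndarray, folds: int,
                   cfg: AnchorConfig | None = None, balance: bool = False,
                   vocab_size: int | None = None, seed: int = 0) -> float:
    """Mean held-out accuracy over stratified folds.

    With ``balance`` the majority class is subsampled to parity before
    folding (mirroring an equal-class test construction, so chance = 0.5).
    """
    cfg = cfg or AnchorConfig()
    if folds < 2:
        raise ValueError("need at least 2 folds")
    y = np.asarray(y)
    X = list(X)
    if balance:
        rng = np.random.default_rng(seed)
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y != 1)
        m = min(len(idx_pos), len(idx_neg))
        keep = np.sort(np.concatenate([
            rng.choice(idx_pos, size=m, replace=False),
            rng.choice(idx_neg, size=m, replace=False)]))
        X = [X[j] for j in keep]
        y = y[keep]
    if len(X) < folds:
        raise ValueError(f"{len(X)} instances cannot fill {folds} folds")
    size = vocab_size if vocab_size is not None else (
        max((max(fs) for fs in X if fs), default=0) + 1)
    M = features_to_csr(X, size)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(M, y):
        lr = LogisticRegression(C=cfg.regularization, solver="liblinear",
                                tol=cfg.tol, random_state=0)
        lr.fit(M[tr], y[tr])
        accs.append(float((lr.predict(M[te]) == y[te]).mean()))
    return float(np.mean(accs))
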