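"""Expected-value scoring and ranking of candidate eligibility criteria.

Given the topic proportions of a small user-supplied sample set D', the
per-topic weights are pooled and normalized into a distribution w~; a
candidate criterion s is then scored by

    sigma(s) = sum_i  w~_i * p_i(T(s) = i)

the probability-weighted sum of normalized topic proportions, where p_i
is the anchored per-topic classifier.  Candidates whose topics dominate
the sample set therefore score highest.  Scores live in [0, 1] because
w~ is a distribution and each p_i is a probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .anchored_training import ClassifierSet
from .corpus_io import (Criterion, CriterionKind, FeatureVector,
                        ProtocolDocument, featurize, tokenize)
from .topic_model import (FittedTopicModel, TopicProportionMatrix,
                          infer_proportions)


@dataclass
class ScoredCriterion:
    criterion: Criterion
    score: float
    position: int  # index of the candidate in the original input order


@dataclass
class RankedCriteria:
    """Candidates of one kind, sorted by score descending."""

    kind: CriterionKind
    items: list[ScoredCriterion]

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def scores(self) -> list[float]:
        return [it.score for it in self.items]


def normalize_weights(W: TopicProportionMatrix | np.ndarray) -> np.ndarray:
    """Pool a sample set's topic proportions into one distribution.

    w~_i = (sum over documents of w_id) / (grand total), so the output is
    non-negative and sums to 1.
    """
    A = W.weights if isinstance(W, TopicProportionMatrix) else np.asarray(W, float)
    if A.ndim == 1:
        A = A[None, :]
    if A.size == 0:
        raise ValueError("empty proportion matrix")
    if (A < 0).any():
        raise ValueError("topic proportions must be non-negative")
    col = A.sum(axis=0)
    total = col.sum()
    if total <= 0:
        raise ValueError("all-zero topic proportions cannot be normalized")
    return col / total


def score_criterion(features: FeatureVector, weights: np.ndarray,
                    classifiers: ClassifierSet) -> float:
    """sigma(s) = sum_i w~_i p_i(s), accumulated left-to-right over topics."""
    if len(weights) != len(classifiers):
        raise ValueError(
            f"{len(weights)} weights vs {len(classifiers)} classifiers")
    s = 0.0
    for i in range(len(weights)):
        s += float(weights[i]) * classifiers.classifiers[i].predict_prob(features)
    return s


def get_score(candidates: Sequence[Criterion],
              docs_by_id: dict[str, ProtocolDocument],
              weights: np.ndarray, classifiers: ClassifierSet,
              feature_mode: str | None = None) -> RankedCriteria:
    """Score every candidate and sort by score descending.

    Ties are broken by (source_id, original position) so the ranking is
    deterministic.  An empty candidate set yields an empty ranking.
    """
    mode = feature_mode or classifiers.feature_mode
    scored = []
    for pos, crit in enumerate(candidates):
        if crit.kind != classifiers.kind:
            raise ValueError(
                f"candidate of kind {crit.kind!r} scored against "
                f"{classifiers.kind!r} classifiers")
        feats = featurize(crit, docs_by_id[crit.source_id], classifiers.vocab,
                          mode=mode)
        scored.append(ScoredCriterion(
            criterion=crit,
            score=score_criterion(feats, weights, classifiers),
            position=pos))
    scored.sort(key=lambda sc: (-sc.score, sc.criterion.source_id, sc.position))
    return RankedCriteria(kind=classifiers.kind, items=scored)


def ldalr_rank(sample_docs: Sequence[ProtocolDocument],
               candidate_docs: Sequence[ProtocolDocument],
               classifiers: ClassifierSet, model: FittedTopicModel,
               feature_mode: str | None = None) -> RankedCriteria:
    """The full ranking step: infer sample-set topics, pool, score, sort.

    The candidate pool is every criterion of the classifier set's kind
    found in ``candidate_docs``, ordered deterministically by
    (source_id, within-document position) before scoring.
    """
    if not sample_docs:
        raise ValueError("sample set D' must be non-empty")
    W = infer_proportions(
        model,
        [tokenize(d.pico_text) for d in sample_docs],
        doc_ids=[d.id for d in sample_docs])
    weights = normalize_weights(W)
    docs_by_id = {d.id: d for d in candidate_docs}
    candidates = [c
                  for d in sorted(candidate_docs, key=lambda d: d.id)
                  for c in d.criteria(classifiers.kind)]
    return get_score(candidates, docs_by_id, weights, classifiers,
                     feature_mode=feature_mode)
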