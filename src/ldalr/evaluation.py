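"""Reconstruction-based evaluation of the ranking pipeline.

A hidden target protocol is drawn from the held-out set; its cosine
neighbors (similarity of full-document term-frequency vectors >= 0.30 by
default) supply both the sample set that drives the ranking and the pool
of candidate criteria.  Four assignment schemes map each target criterion
to a candidate:

* LMT — theoretical limit: per-target best candidate from the *full*
  pool (reuse allowed); no algorithm can beat it.
* RND — uniform random candidate from the full pool per target.
* ITR — per-target best candidate from the top fraction of the ranked
  list (reuse allowed; may fail to be an injective solution).
* BFS — greedy best-first injective matching on the same restricted pool
  (always a solution, not necessarily optimal).

Per-method mean similarities are aggregated over observation points and
reported raw, normalized to LMT = 100, and as a percentage of RND.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .anchored_training import ClassifierSet
from .corpus_io import Criterion, CriterionKind, ProtocolDocument, tokenize
from .scoring import RankedCriteria, ldalr_rank
from .topic_model import FittedTopicModel

logger = logging.getLogger(__name__)

METHODS = ("LMT", "ITR", "BFS", "RND")


# ---------------------------------------------------------------- similarity

def _counter_cosine(a: Counter, b: Counter) -> float:
    if not a or not b:
        return 0.0
    if len(b) < len(a):
        a, b = b, a
    dot = sum(v * b[t] for t, v in a.items() if t in b)
    if dot == 0:
        return 0.0
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    return dot / (na * nb)


def document_cosine(a: ProtocolDocument, b: ProtocolDocument) -> float:
    """Cosine of raw term-frequency vectors over the entire document text."""
    return _counter_cosine(Counter(tokenize(a.full_text)),
                           Counter(tokenize(b.full_text)))


def criterion_cosine(s1: Criterion, s2: Criterion) -> float:
    """Cosine of term-frequency vectors over the criterion texts."""
    return _counter_cosine(Counter(tokenize(s1.text)),
                           Counter(tokenize(s2.text)))


def select_neighbors(d_tau: ProtocolDocument,
                     corpus: Sequence[ProtocolDocument],
                     threshold: float = 0.30) -> list[ProtocolDocument]:
    """Documents (other than the target itself) with cosine >= threshold."""
    return [d for d in corpus
            if d.id != d_tau.id and document_cosine(d_tau, d) >= threshold]


def similarity_matrix(targets: Sequence[Criterion],
                      pool: Sequence[Criterion],
                      phi: Callable[[Criterion, Criterion], float]
                      = criterion_cosine) -> np.ndarray:
    """Targets x candidates similarity matrix, with per-text token caching."""
    t_vecs = [Counter(tokenize(t.text)) for t in targets]
    p_vecs = [Counter(tokenize(c.text)) for c in pool]
    if phi is criterion_cosine:
        M = np.empty((len(targets), len(pool)))
        for i, tv in enumerate(t_vecs):
            for j, pv in enumerate(p_vecs):
                M[i, j] = _counter_cosine(tv, pv)
        return M
    return np.array([[phi(t, c) for c in pool] for t in targets])


# ---------------------------------------------------------------- assignments

@dataclass
class Assignment:
    """A mapping g from each target criterion to a chosen candidate index."""

    method: str
    mapping: list[int]
    sims: list[float]
    is_solution: bool

    @property
    def mean(self) -> float:
        return float(np.mean(self.sims))


def _require_nonempty(M: np.ndarray) -> None:
    if M.shape[0] == 0:
        raise ValueError("no target criteria: mean similarity undefined")
    if M.shape[1] == 0:
        raise ValueError("empty candidate pool")


def assign_per_target_max(M: np.ndarray, method: str = "LMT") -> Assignment:
    """Per-target argmax with reuse allowed; first-maximum tie-break follows
    the pool's deterministic order."""
    M = np.asarray(M, float)
    _require_nonempty(M)
    mapping = [int(np.argmax(M[i])) for i in range(M.shape[0])]
    sims = [float(M[i, j]) for i, j in enumerate(mapping)]
    return Assignment(method=method, mapping=mapping, sims=sims,
                      is_solution=len(set(mapping)) == len(mapping))


def assign_random(M: np.ndarray, seed: int) -> Assignment:
    """Uniform random candidate from the full pool, per target."""
    M = np.asarray(M, float)
    _require_nonempty(M)
    rng = np.random.default_rng(seed)
    mapping = rng.integers(0, M.shape[1], size=M.shape[0]).tolist()
    sims = [float(M[i, j]) for i, j in enumerate(mapping)]
    return Assignment(method="RND", mapping=mapping, sims=sims,
                      is_solution=len(set(mapping)) == len(mapping))


def assign_greedy_injective(M: np.ndarray) -> Assignment:
    """Best-first greedy injective matching.

    Repeatedly commits the (unassigned target, unused candidate) pair of
    globally maximal similarity; ties resolve to the earliest target, then
    the earliest candidate (row-major first maximum).  When the pool is
    smaller than the target set, used candidates are recycled once the
    pool is exhausted (logged).
    """
    M = np.asarray(M, float)
    _require_nonempty(M)
    n_t, n_c = M.shape
    if n_c < n_t:
        logger.warning("pool (%d) smaller than target set (%d); candidates "
                       "will be recycled", n_c, n_t)
    work = M.copy()
    NEG = -np.inf
    mapping = [-1] * n_t
    used_cols: set[int] = set()
    for _ in range(n_t):
        if len(used_cols) == n_c:        # recycle the exhausted pool
            used_cols.clear()
            work = M.copy()
            work[[i for i, m in enumerate(mapping) if m >= 0], :] = NEG
        i, j = np.unravel_index(int(np.argmax(work)), work.shape)
        mapping[i] = int(j)
        work[i, :] = NEG
        work[:, j] = NEG
        used_cols.add(int(j))
    sims = [float(M[i, j]) for i, j in enumerate(mapping)]
    return Assignment(method="BFS", mapping=mapping, sims=sims,
                      is_solution=n_c >= n_t)


def lmt_assign(targets: Sequence[Criterion], pool: Sequence[Criterion],
               phi: Callable = criterion_cosine) -> Assignment:
    return assign_per_target_max(similarity_matrix(targets, pool, phi), "LMT")


def rnd_assign(targets: Sequence[Criterion], pool: Sequence[Criterion],
               seed: int, phi: Callable = criterion_cosine) -> Assignment:
    return assign_random(similarity_matrix(targets, pool, phi), seed)


def itr_assign(targets: Sequence[Criterion], pool: Sequence[Criterion],
               phi: Callable = criterion_cosine) -> Assignment:
    a = assign_per_target_max(similarity_matrix(targets, pool, phi), "ITR")
    return a


def bfs_assign(targets: Sequence[Criterion], pool: Sequence[Criterion],
               phi: Callable = criterion_cosine) -> Assignment:
    return assign_greedy_injective(similarity_matrix(targets, pool, phi))


def restrict_top_fraction(ranked: RankedCriteria, fraction: float = 0.30
                          ) -> list[int]:
    """Original-pool indices of the top ceil(fraction * |ranked|) criteria."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(ranked) == 0:
        raise ValueError("cannot restrict an empty ranking")
    k = math.ceil(fraction * len(ranked))
    return [sc.position for sc in ranked.items[:k]]


# ------------------------------------------------------------- aggregation

def summarize(avg_sims: dict[str, float]) -> dict[str, dict[str, float]]:
    """Normalized (LMT = 100) and percent-vs-random (RND = 100) rows from
    unrounded per-method averages."""
    lmt = avg_sims["LMT"]
    rnd = avg_sims["RND"]
    if lmt <= 0 or rnd <= 0:
        raise ValueError("LMT and RND averages must be positive to normalize")
    out = {}
    for m, v in avg_sims.items():
        normalized = 100.0 * v / lmt
        out[m] = {"avg_sim": v,
                  "normalized": normalized,
                  "pct_vs_random": 100.0 * v / rnd}
    return out


@dataclass
class EvaluationSummary:
    kind: CriterionKind
    n_topics: int
    points: int
    skipped: int
    avg_sim: dict[str, float]
    normalized: dict[str, float]
    pct_vs_random: dict[str, float]
    mean_neighbors: float
    mean_targets: float
    mean_candidates: float

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "n_topics": self.n_topics,
            "points": self.points, "skipped": self.skipped,
            "avg_sim": self.avg_sim, "normalized": self.normalized,
            "pct_vs_random": self.pct_vs_random,
            "mean_neighbors": self.mean_neighbors,
            "mean_targets": self.mean_targets,
            "mean_candidates": self.mean_candidates,
        }


@dataclass
class ObservationPoint:
    """Bookkeeping for one reconstruction task (one target, one kind)."""

    target_id: str
    kind: CriterionKind
    n_neighbors: int
    n_targets: int
    n_candidates: int
    means: dict[str, float]
    is_solution: dict[str, bool] = field(default_factory=dict)


def evaluate_target(d_tau: ProtocolDocument, kind: CriterionKind,
                    corpus: Sequence[ProtocolDocument],
                    model: FittedTopicModel, classifiers: ClassifierSet,
                    neighbor_threshold: float = 0.30,
                    top_fraction: float = 0.30,
                    rnd_seed: int = 0,
                    feature_mode: str | None = None
                    ) -> ObservationPoint | None:
    """Run all four assignment schemes on one hidden target.

    Returns None (a skip) when the target has no criteria of the kind, no
    neighbors pass the threshold, or the neighbors carry no candidates.
    """
    targets = d_tau.criteria(kind)
    if not targets:
        return None
    neighbors = select_neighbors(d_tau, corpus, neighbor_threshold)
    if not neighbors:
        logger.warning("target %s has no neighbors at threshold %.2f; skipped",
                       d_tau.id, neighbor_threshold)
        return None
    ranked = ldalr_rank(neighbors, neighbors, classifiers, model,
                        feature_mode=feature_mode)
    if len(ranked) == 0:
        logger.warning("target %s: neighbor pool has no %s criteria; skipped",
                       d_tau.id, kind)
        return None
    # pool in the deterministic order ldalr_rank used for positions
    pool = [c for d in sorted(neighbors, key=lambda d: d.id)
            for c in d.criteria(kind)]
    M = similarity_matrix(targets, pool)
    top_idx = restrict_top_fraction(ranked, top_fraction)
    M_top = M[:, top_idx]

    lmt = assign_per_target_max(M, "LMT")
    rnd = assign_random(M, rnd_seed)
    itr = assign_per_target_max(M_top, "ITR")
    bfs = assign_greedy_injective(M_top)
    return ObservationPoint(
        target_id=d_tau.id, kind=kind,
        n_neighbors=len(neighbors), n_targets=len(targets),
        n_candidates=len(pool),
        means={"LMT": lmt.mean, "RND": rnd.mean,
               "ITR": itr.mean, "BFS": bfs.mean},
        is_solution={"LMT": lmt.is_solution, "RND": rnd.is_solution,
                     "ITR": itr.is_solution, "BFS": bfs.is_solution})


def run_reconstruction(targets: Sequence[ProtocolDocument],
                       corpus: Sequence[ProtocolDocument],
                       model: FittedTopicModel,
                       classifier_sets: dict[CriterionKind, ClassifierSet],
                       n_points: int | None = None,
                       seed: int = 0,
                       neighbor_threshold: float = 0.30,
                       top_fraction: float = 0.30,
                       feature_mode: str | None = None,
                       ) -> tuple[dict[CriterionKind, EvaluationSummary],
                                  list[ObservationPoint]]:
    """Sample observation points from the held-out targets and aggregate.

    Each sampled target contributes one observation point per criterion
    kind for which it has criteria and candidates.  Normalized and
    percent-of-random rows are computed from the unrounded averages.
    """
    rng = np.random.default_rng(seed)
    targets = list(targets)
    if n_points is not None and n_points < len(targets):
        pick = rng.choice(len(targets), size=n_points, replace=False)
        targets = [targets[i] for i in sorted(pick)]
    records: list[ObservationPoint] = []
    skipped = {k: 0 for k in classifier_sets}
    for d_tau in targets:
        for kind, cset in classifier_sets.items():
            rec = evaluate_target(
                d_tau, kind, corpus, model, cset,
                neighbor_threshold=neighbor_threshold,
                top_fraction=top_fraction,
                rnd_seed=int(rng.integers(2 ** 31)),
                feature_mode=feature_mode)
            if rec is None:
                skipped[kind] += 1
            else:
                records.append(rec)
    summaries: dict[CriterionKind, EvaluationSummary] = {}
    for kind in classifier_sets:
        recs = [r for r in records if r.kind == kind]
        if not recs:
            continue
        avg = {m: float(np.mean([r.means[m] for r in recs])) for m in METHODS}
        rows = summarize(avg)
        summaries[kind] = EvaluationSummary(
            kind=kind, n_topics=model.n_topics, points=len(recs),
            skipped=skipped[kind],
            avg_sim=avg,
            normalized={m: rows[m]["normalized"] for m in METHODS},
            pct_vs_random={m: rows[m]["pct_vs_random"] for m in METHODS},
            mean_neighbors=float(np.mean([r.n_neighbors for r in recs])),
            mean_targets=float(np.mean([r.n_targets for r in recs])),
            mean_candidates=float(np.mean([r.n_candidates for r in recs])))
    return summaries, records


def sweep_topics(n_values: Sequence[int],
                 train_docs: Sequence[ProtocolDocument],
                 target_docs: Sequence[ProtocolDocument],
                 kinds: Sequence[CriterionKind] = ("inclusion", "exclusion"),
                 seed: int = 0,
                 anchor_cfg=None,
                 n_points: int | None = None,
                 neighbor_threshold: float = 0.30,
                 top_fraction: float = 0.30,
                 iterations: int = 50,
                 ) -> list[dict]:
    """Re-run the full pipeline for each topic count n with shared seeds.

    Returns one entry per n with the per-kind evaluation summaries, the
    series behind a normalized-similarity-versus-n curve.
    """
    from .anchored_training import AnchorConfig, anchor_train
    from .corpus_io import build_vocabulary
    from .topic_model import TopicModelParams, fit_topic_model, infer_proportions

    if len(n_values) < 2:
        raise ValueError("a sweep needs at least 2 topic counts")
    anchor_cfg = anchor_cfg or AnchorConfig(seed=seed)
    pico_tokens = [tokenize(d.pico_text) for d in train_docs]
    feat_vocab = build_vocabulary(
        [tokenize(d.full_text) for d in train_docs])
    series = []
    for n in n_values:
        model = fit_topic_model(pico_tokens,
                                TopicModelParams(n=n, seed=seed,
                                                 iterations=iterations))
        W = infer_proportions(model, pico_tokens,
                              doc_ids=[d.id for d in train_docs])
        csets = {kind: anchor_train(train_docs, W, anchor_cfg, kind,
                                    feat_vocab)
                 for kind in kinds}
        summaries, _ = run_reconstruction(
            target_docs, train_docs, model, csets, n_points=n_points,
            seed=seed, neighbor_threshold=neighbor_threshold,
            top_fraction=top_fraction)
        series.append({"n": n,
                       "summaries": {k: s.to_dict()
                                     for k, s in summaries.items()}})
    return series
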