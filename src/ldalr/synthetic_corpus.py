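"""Synthetic protocol corpora with known (planted) topic structure.

The generator realizes the generative story the recommender assumes:
each document carries a Dirichlet-drawn mixture over K latent topics;
its PICO text and each of its eligibility criteria are emitted from the
mixture of topic-specific word distributions.  Topic vocabularies are
disjoint letter-only token blocks by default (an ``overlap`` knob blends
in a shared block to make topics harder to separate, up to
indistinguishable as overlap -> 1).  Criterion texts additionally mix in
a shared noise vocabulary so that criteria carry recoverable but
imperfect topic signal, mimicking the noise inherent in topic
pseudo-labels.

Corpus statistics emulate real registry protocols: roughly 12 criteria
per document of which about 39% are inclusion criteria (so ~5 inclusion
and ~7 exclusion on average).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .corpus_io import Criterion, ProtocolDocument
from .topic_model import TopicProportionMatrix

_LETTERS = string.ascii_lowercase


def _code(i: int, width: int = 3) -> str:
    out = []
    for _ in range(width):
        out.append(_LETTERS[i % 26])
        i //= 26
    return "".join(reversed(out))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults define the standard study conditions."""

    K: int = 10                      # true number of topics
    vocab_per_topic: int = 200       # tokens in each topic's block
    docs: int = 500
    alpha: float = 0.1               # Dirichlet concentration of mixtures
    pico_tokens: int = 80            # tokens of PICO text per document
    criterion_tokens: int = 8        # tokens per criterion
    mean_criteria: float = 12.0      # mean total criteria per document
    inclusion_fraction: float = 0.39
    noise_fraction: float = 0.2      # criterion tokens drawn off-topic
    noise_vocab: int = 200           # size of the shared noise block
    overlap: float = 0.0             # topic-word mass on the shared block
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("need K >= 2 topics")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if min(self.vocab_per_topic, self.docs, self.pico_tokens,
               self.criterion_tokens, self.noise_vocab) < 1:
            raise ValueError("all counts must be positive")
        if not 0 < self.inclusion_fraction < 1:
            raise ValueError("inclusion_fraction must be in (0, 1)")


@dataclass
class SyntheticCorpus:
    spec: SyntheticSpec
    documents: list[ProtocolDocument]
    ground_truth: np.ndarray = field(repr=False)       # (docs, K) mixtures
    topic_vocabularies: list[list[str]] = field(repr=False)
    noise_vocabulary: list[str] = field(repr=False)
    shared_vocabulary: list[str] = field(repr=False)


def _topic_blocks(spec: SyntheticSpec) -> tuple[list[list[str]], list[str], list[str]]:
    topics = [[f"w{_code(t, 2)}{_code(i)}" for i in range(spec.vocab_per_topic)]
              for t in range(spec.K)]
    noise = [f"qn{_code(i)}x" for i in range(spec.noise_vocab)]
    shared = [f"qs{_code(i)}z" for i in range(spec.vocab_per_topic)]
    return topics, noise, shared


def _draw_topic_tokens(rng: np.random.Generator, theta: np.ndarray,
                       n: int, topics: list[list[str]], shared: list[str],
                       overlap: float) -> list[str]:
    ks = rng.choice(len(theta), size=n, p=theta)
    toks = []
    for k in ks:
        if overlap > 0 and rng.random() < overlap:
            block = shared
        else:
            block = topics[k]
        toks.append(block[rng.integers(len(block))])
    return toks


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate a corpus of protocol documents; fully seed-reproducible."""
    rng = np.random.default_rng(spec.seed)
    topics, noise, shared = _topic_blocks(spec)
    docs: list[ProtocolDocument] = []
    truth = np.empty((spec.docs, spec.K))
    for d in range(spec.docs):
        doc_id = f"SYN{d:05d}"
        theta = rng.dirichlet(np.full(spec.K, spec.alpha))
        truth[d] = theta
        pico_toks = _draw_topic_tokens(rng, theta, spec.pico_tokens,
                                       topics, shared, spec.overlap)
        # spread PICO tokens over the four roles: half to P, rest split
        cut1 = spec.pico_tokens // 2
        cut2 = cut1 + (spec.pico_tokens - cut1) // 3
        cut3 = cut2 + (spec.pico_tokens - cut1) // 3
        pico = {"P": " ".join(pico_toks[:cut1]),
                "I": " ".join(pico_toks[cut1:cut2]),
                "C": " ".join(pico_toks[cut2:cut3]),
                "O": " ".join(pico_toks[cut3:])}
        pico = {k: v for k, v in pico.items() if v}

        n_crit = max(1, int(rng.poisson(spec.mean_criteria)))
        inclusion, exclusion = [], []
        for _ in range(n_crit):
            n_noise = int(rng.binomial(spec.criterion_tokens,
                                       spec.noise_fraction))
            toks = [noise[rng.integers(len(noise))] for _ in range(n_noise)]
            toks += _draw_topic_tokens(rng, theta,
                                       spec.criterion_tokens - n_noise,
                                       topics, shared, spec.overlap)
            kind = ("inclusion" if rng.random() < spec.inclusion_fraction
                    else "exclusion")
            crit = Criterion(" ".join(toks) if toks else "empty",
                             kind, doc_id)
            (inclusion if kind == "inclusion" else exclusion).append(crit)
        docs.append(ProtocolDocument(id=doc_id, pico=pico,
                                     inclusion=inclusion,
                                     exclusion=exclusion))
    return SyntheticCorpus(spec=spec, documents=docs, ground_truth=truth,
                           topic_vocabularies=topics,
                           noise_vocabulary=noise, shared_vocabulary=shared)


def ground_truth_proportions(corpus: SyntheticCorpus) -> TopicProportionMatrix:
    """The generating mixtures in the same shape the topic model emits."""
    return TopicProportionMatrix(
        doc_ids=[d.id for d in corpus.documents],
        weights=corpus.ground_truth)


def match_topics(topic_word: np.ndarray, vocab_index_to_token: list[str],
                 corpus: SyntheticCorpus) -> np.ndarray:
    """Greedy relabeling of fitted topics onto generator topics.

    Returns a permutation array ``perm`` with ``perm[fitted] = true``:
    each fitted topic is assigned, in order of decreasing confidence, to
    the unclaimed true topic on whose vocabulary block it places the most
    probability mass.  Bijective when the fitted topic count equals K.
    """
    K = corpus.spec.K
    n = topic_word.shape[0]
    block_of = {}
    for t, block in enumerate(corpus.topic_vocabularies):
        for w in block:
            block_of[w] = t
    mass = np.zeros((n, K))
    for j, tok in enumerate(vocab_index_to_token):
        t = block_of.get(tok)
        if t is not None:
            mass[:, t] += topic_word[:, j]
    perm = np.full(n, -1)
    taken: set[int] = set()
    # highest-mass (fitted, true) pairs claimed first
    order = np.argsort(-mass, axis=None)
    for flat in order:
        f, t = divmod(int(flat), K)
        if perm[f] == -1 and t not in taken:
            perm[f] = t
            taken.add(t)
            if len(taken) == min(n, K):
                break
    # leftovers (n > K) map to their best block regardless of claims
    for f in range(n):
        if perm[f] == -1:
            perm[f] = int(np.argmax(mass[f]))
    return perm
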