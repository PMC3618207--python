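import numpy as np
import pytest

from ldalr import (AnchorConfig, SyntheticSpec, anchor_train,
                   build_vocabulary, fit_topic_model, generate_corpus,
                   infer_proportions, split_corpus, tokenize,
                   TopicModelParams)


@pytest.fixture(scope="session")
def small_corpus():
    """A small well-separated 3-topic corpus for fast unit tests."""
    return generate_corpus(SyntheticSpec(
        K=3, vocab_per_topic=60, docs=80, pico_tokens=40,
        mean_criteria=8, seed=42))


@pytest.fixture(scope="session")
def small_fit(small_corpus):
    """Matched-n topic model fitted on the small corpus."""
    toks = [tokenize(d.pico_text) for d in small_corpus.documents]
    model = fit_topic_model(toks, TopicModelParams(n=3, seed=0, iterations=30))
    W = infer_proportions(model, toks,
                          doc_ids=[d.id for d in small_corpus.documents])
    return model, W


@pytest.fixture(scope="session")
def default_pipeline():
    """Full pipeline artifacts under the standard study conditions
    (K=10, 500 documents), shared by the heavier end-to-end tests."""
    seed = 11
    corpus = generate_corpus(SyntheticSpec(seed=seed))
    train, test = split_corpus(corpus.documents, 0.1, seed)
    pico = [tokenize(d.pico_text) for d in train]
    model = fit_topic_model(pico, TopicModelParams(n=10, seed=seed))
    W = infer_proportions(model, pico, doc_ids=[d.id for d in train])
    vocab = build_vocabulary([tokenize(d.full_text) for d in train])
    cfg = AnchorConfig(seed=seed)
    csets = {kind: anchor_train(train, W, cfg, kind, vocab)
             for kind in ("inclusion", "exclusion")}
    return {"corpus": corpus, "train": train, "test": test, "model": model,
            "W": W, "vocab": vocab, "cfg": cfg, "csets": csets, "seed": seed}
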