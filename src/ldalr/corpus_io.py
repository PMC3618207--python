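"""Parsing, tokenization and featurization of clinical-trial protocol records.

A protocol record is an XML study record in the public-registry dialect.
Free text is pulled from a fixed set of tags and grouped into the four
PICO roles (Patient/problem, Intervention, Comparison, Outcome); the
eligibility text block is segmented into individual inclusion and
exclusion criteria.  Tokenization is deliberately plain: lowercase
unigrams, punctuation acts as a separator, tokens containing digits and
stopwords are dropped, and no stemming is applied.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
from lxml import etree

from .stopwords import STOPWORDS

logger = logging.getLogger(__name__)

CriterionKind = Literal["inclusion", "exclusion"]

#: registry XML tags feeding each PICO role
PICO_TAGS: dict[str, tuple[str, ...]] = {
    "P": ("brief_summary", "detailed_description", "condition",
          "official_title", "brief_title"),
    "I": ("intervention",),
    "C": ("arm_group",),
    "O": ("primary_outcome", "secondary_outcome"),
}

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_DIGIT_RE = re.compile(r"\d")
_HEADING_RE = re.compile(r"(inclusion|exclusion)\s+criteria\s*:?", re.IGNORECASE)
_BULLET_RE = re.compile(r"^\s*(?:[-*•·]|\d+[.)])\s+")


@dataclass(frozen=True)
class Criterion:
    """One eligibility criterion; belongs to exactly one kind."""

    text: str
    kind: CriterionKind
    source_id: str

    def __post_init__(self) -> None:
        if self.kind not in ("inclusion", "exclusion"):
            raise ValueError(f"invalid criterion kind: {self.kind!r}")
        if not self.text.strip():
            raise ValueError("criterion text is empty")


@dataclass
class ProtocolDocument:
    """A clinical-trial protocol: PICO sections plus its eligibility criteria."""

    id: str
    pico: dict[str, str] = field(default_factory=dict)
    inclusion: list[Criterion] = field(default_factory=list)
    exclusion: list[Criterion] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.pico) - {"P", "I", "C", "O"}
        if bad:
            raise ValueError(f"unknown PICO roles: {sorted(bad)}")
        for c in self.inclusion:
            if c.kind != "inclusion":
                raise ValueError("inclusion list holds a non-inclusion criterion")
        for c in self.exclusion:
            if c.kind != "exclusion":
                raise ValueError("exclusion list holds a non-exclusion criterion")

    @property
    def pico_text(self) -> str:
        """All PICO free text in fixed role order."""
        return " ".join(self.pico.get(k, "") for k in "PICO").strip()

    @property
    def full_text(self) -> str:
        """All textual content: PICO sections plus every criterion."""
        parts = [self.pico_text]
        parts.extend(c.text for c in self.inclusion)
        parts.extend(c.text for c in self.exclusion)
        return " ".join(p for p in parts if p)

    def criteria(self, kind: CriterionKind) -> list[Criterion]:
        return self.inclusion if kind == "inclusion" else self.exclusion

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "pico": {k: self.pico.get(k, "") for k in "PICO"},
            "inclusion": [c.text for c in self.inclusion],
            "exclusion": [c.text for c in self.exclusion],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolDocument":
        doc_id = d["id"]
        return cls(
            id=doc_id,
            pico={k: v for k, v in d.get("pico", {}).items() if v},
            inclusion=[Criterion(t, "inclusion", doc_id) for t in d.get("inclusion", [])],
            exclusion=[Criterion(t, "exclusion", doc_id) for t in d.get("exclusion", [])],
        )


class Vocabulary:
    """Bidirectional token <-> contiguous index map, lexicographically ordered."""

    def __init__(self, tokens: Sequence[str]):
        self.index_to_token: list[str] = sorted(set(tokens))
        self.token_to_index: dict[str, int] = {
            t: i for i, t in enumerate(self.index_to_token)
        }

    def __len__(self) -> int:
        return len(self.index_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def __getitem__(self, token: str) -> int:
        return self.token_to_index[token]

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, Vocabulary)
                and self.index_to_token == other.index_to_token)

    def fingerprint(self) -> str:
        import hashlib
        return hashlib.sha256("\n".join(self.index_to_token).encode()).hexdigest()


#: a feature vector is the set of vocabulary indices present (binary encoding)
FeatureVector = frozenset


def tokenize(text: str, stopwords: frozenset[str] = STOPWORDS) -> list[str]:
    """Lowercased unigrams; punctuation splits, digit-bearing tokens and
    stopwords are dropped, no stemming."""
    out = []
    for tok in _TOKEN_RE.findall(text.lower()):
        if _DIGIT_RE.search(tok):
            continue
        if tok in stopwords:
            continue
        out.append(tok)
    return out


def _tag_text(root: etree._Element, tag: str) -> str:
    chunks = []
    for el in root.iter(tag):
        t = " ".join(el.itertext()).strip()
        if t:
            chunks.append(re.sub(r"\s+", " ", t))
    return " ".join(chunks)


def parse_protocol_record(raw: str | bytes, record_id: str | None = None
                          ) -> ProtocolDocument:
    """Parse one registry-style XML study record.

    PICO sections follow the fixed tag mapping in :data:`PICO_TAGS`; the
    eligibility criteria text block (``eligibility//textblock`` or the
    ``criteria`` element) is segmented into individual criteria.  Missing
    tags yield empty sections, never errors.
    """
    if isinstance(raw, str):
        raw = raw.encode("utf-8")
    try:
        root = etree.fromstring(raw)
    except etree.XMLSyntaxError as exc:
        raise ValueError(
            f"malformed XML for record {record_id or '<unknown>'}: {exc}"
        ) from exc

    doc_id = record_id or _tag_text(root, "nct_id") or _tag_text(root, "id") or "record"

    pico = {}
    for role, tags in PICO_TAGS.items():
        text = " ".join(t for t in (_tag_text(root, tag) for tag in tags) if t)
        if text:
            pico[role] = text

    elig_text = ""
    for el in root.iter("eligibility"):
        tb = el.find(".//textblock")
        elig_text = " \n".join((el.itertext())) if tb is None else "\n".join(tb.itertext())
        break
    if not elig_text:
        for el in root.iter("criteria"):
            elig_text = "\n".join(el.itertext())
            break

    if elig_text.strip():
        inclusion, exclusion = segment_criteria(elig_text, source_id=doc_id)
    else:
        logger.warning("record %s has no eligibility block", doc_id)
        inclusion, exclusion = [], []

    return ProtocolDocument(id=doc_id, pico=pico,
                            inclusion=inclusion, exclusion=exclusion)


def segment_criteria(eligibility_textblock: str, source_id: str = ""
                     ) -> tuple[list[Criterion], list[Criterion]]:
    """Split an eligibility text block into inclusion and exclusion criteria.

    The block is cut at ``Inclusion Criteria`` / ``Exclusion Criteria``
    headings (case-insensitive, optional colon); within each section,
    top-level bullet items (``-``, ``*``, bullet glyphs, or ``1.``/``1)``
    numbering) become individual criteria, with unmarked continuation lines
    folded into the preceding bullet.  A section with content but no
    bullets becomes a single criterion.  Without any heading nothing is
    produced (the kind cannot be guessed) and a warning is logged.
    """
    matches = list(_HEADING_RE.finditer(eligibility_textblock))
    if not matches:
        if eligibility_textblock.strip():
            logger.warning(
                "no inclusion/exclusion heading in eligibility block of %s; "
                "no criteria extracted", source_id or "<unknown>")
        return [], []

    out: dict[str, list[Criterion]] = {"inclusion": [], "exclusion": []}
    for m, nxt in zip(matches, matches[1:] + [None]):
        kind = m.group(1).lower()
        end = nxt.start() if nxt is not None else len(eligibility_textblock)
        section = eligibility_textblock[m.end():end]
        for text in _split_bullets(section):
            out[kind].append(Criterion(text, kind, source_id))  # type: ignore[arg-type]
    return out["inclusion"], out["exclusion"]


def _split_bullets(section: str) -> list[str]:
    items: list[str] = []
    current: list[str] = []
    saw_bullet = False
    for line in section.splitlines():
        if _BULLET_RE.match(line):
            if current:
                items.append(" ".join(current))
            current = [_BULLET_RE.sub("", line).strip()]
            saw_bullet = True
        elif line.strip() and saw_bullet:
            current.append(line.strip())
    if current:
        items.append(" ".join(current))
    if not saw_bullet:
        whole = re.sub(r"\s+", " ", section).strip()
        if whole:
            items = [whole]
    return [t for t in (i.strip() for i in items) if t]


def build_vocabulary(token_lists: Iterable[Sequence[str]], min_count: int = 1
                     ) -> Vocabulary:
    """Vocabulary of all tokens with corpus frequency >= ``min_count``."""
    counts: Counter[str] = Counter()
    n_docs = 0
    for toks in token_lists:
        counts.update(toks)
        n_docs += 1
    if n_docs == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return Vocabulary([t for t, c in counts.items() if c >= min_count])


def featurize(criterion: Criterion, source: ProtocolDocument, vocab: Vocabulary,
              mode: str = "criterion+pico") -> FeatureVector:
    """Binary feature set for one criterion.

    Default mode unions the criterion's tokens with the PICO tokens of its
    own source document; ``criterion-only`` uses the criterion text alone.
    Out-of-vocabulary tokens are silently dropped.
    """
    if criterion.source_id != source.id:
        raise ValueError(
            f"criterion from {criterion.source_id!r} featurized against "
            f"document {source.id!r}")
    toks = tokenize(criterion.text)
    if mode == "criterion+pico":
        toks = toks + tokenize(source.pico_text)
    elif mode != "criterion-only":
        raise ValueError(f"unknown feature mode: {mode!r}")
    return frozenset(vocab[t] for t in toks if t in vocab)


def split_corpus(corpus: Sequence[ProtocolDocument], test_fraction: float,
                 seed: int) -> tuple[list[ProtocolDocument], list[ProtocolDocument]]:
    """Disjoint, exhaustive train/test partition, reproducible under seed."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if len(corpus) < 2:
        raise ValueError("corpus must contain at least 2 documents to split")
    n_test = int(round(test_fraction * len(corpus)))
    n_test = max(1, min(len(corpus) - 1, n_test))
    order = np.random.default_rng(seed).permutation(len(corpus))
    test_idx = set(order[:n_test].tolist())
    train = [corpus[i] for i in range(len(corpus)) if i not in test_idx]
    test = [corpus[i] for i in range(len(corpus)) if i in test_idx]
    return train, test


def write_jsonl(docs: Iterable[ProtocolDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc.to_dict(), sort_keys=True) + "\n")


def read_jsonl(path: str | Path) -> list[ProtocolDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                docs.append(ProtocolDocument.from_dict(json.loads(line)))
    return docs


def iter_xml_records(path: str | Path) -> Iterator[ProtocolDocument]:
    """Parse every ``*.xml`` file under a directory (or a single file)."""
    path = Path(path)
    files = sorted(path.glob("*.xml")) if path.is_dir() else [path]
    for f in files:
        yield parse_protocol_record(f.read_bytes(), record_id=f.stem)
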