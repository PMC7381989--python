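"""Retrieval-based diabetes question answering.

A self-contained FAQ engine: question/answer pairs are indexed offline as
L2-normalised TF-IDF vectors over their questions, and at query time the
user's question is embedded the same way and scored by cosine similarity
against every stored question.  The best-scoring answer is returned when its
score clears a threshold; otherwise the engine reports "no answer", which in
practice means the question is off-topic for the knowledge base.

Weighting is pinned exactly so behaviour is reproducible:
``tf = raw term count`` and ``idf = ln((1 + N) / (1 + df)) + 1`` with N pairs
and df the number of questions containing the term; rows are L2-normalised.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Union

import numpy as np

from .errors import DomainError

DEFAULT_THRESHOLD = 0.3
DEFAULT_TOP_N = 3

#: Small English stopword list; enough to drop function words from FAQ text.
STOPWORDS = frozenset(
    """
    a about above after again all am an and any are as at be because been
    before being below between both but by can could did do does doing down
    during each few for from further had has have having he her here hers
    him his how i if in into is it its itself just me more most my myself
    no nor not of off on once only or other our ours out over own same she
    should so some such than that the their theirs them then there these
    they this those through to too under until up very was we were what
    when where which while who whom why will with you your yours
    """.split()
)

_PUNCT_TABLE = str.maketrans({ch: " " for ch in string.punctuation})


@dataclass(frozen=True)
class QAPair:
    """One stored question with its answer and provenance."""

    question: str
    answer: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.question.strip():
            raise DomainError("question must be non-empty")
        if not self.answer.strip():
            raise DomainError("answer must be non-empty")


@dataclass(frozen=True)
class AnswerResult:
    """Outcome of a query: best answer (or none) plus the ranked list."""

    status: str  # "answered" | "no_answer"
    answer: Optional[str]
    score: float
    ranked: tuple[tuple[QAPair, float], ...]

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "answer": self.answer,
            "score": self.score,
            "ranked": [
                {"question": p.question, "answer": p.answer, "score": s}
                for p, s in self.ranked
            ],
        }


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace, drop stopwords."""
    terms = text.lower().translate(_PUNCT_TABLE).split()
    return [t for t in terms if t not in STOPWORDS]


@dataclass
class KnowledgeBase:
    """Indexed Q&A pairs: vocabulary, idf weights, unit-norm question rows."""

    pairs: tuple[QAPair, ...]
    vocabulary: dict[str, int]
    idf: np.ndarray
    question_vectors: np.ndarray  # (N, |V|), rows L2-normalised (or zero)

    def vectorize(self, text: str) -> np.ndarray:
        """TF-IDF embed arbitrary text with the stored vocabulary and idf."""
        vec = np.zeros(len(self.vocabulary))
        for term in tokenize(text):
            j = self.vocabulary.get(term)
            if j is not None:
                vec[j] += 1.0
        vec *= self.idf
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def build_index(pairs: Iterable[QAPair]) -> KnowledgeBase:
    """Index pairs: tf = raw count, idf = ln((1+N)/(1+df)) + 1, L2 rows."""
    pairs = tuple(pairs)
    if not pairs:
        raise DomainError("cannot index an empty pair list")
    token_lists = [tokenize(p.question) for p in pairs]
    vocabulary: dict[str, int] = {}
    for terms in token_lists:
        for t in terms:
            if t not in vocabulary:
                vocabulary[t] = len(vocabulary)
    n = len(pairs)
    counts = np.zeros((n, len(vocabulary)))
    for i, terms in enumerate(token_lists):
        for t in terms:
            counts[i, vocabulary[t]] += 1.0
    df = (counts > 0).sum(axis=0)
    idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    vectors = counts * idf
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    np.divide(vectors, norms, out=vectors, where=norms > 0)
    return KnowledgeBase(
        pairs=pairs, vocabulary=vocabulary, idf=idf, question_vectors=vectors
    )


def answer(
    query: str,
    kb: KnowledgeBase,
    threshold: float = DEFAULT_THRESHOLD,
    top_n: int = DEFAULT_TOP_N,
) -> AnswerResult:
    """Rank stored questions by cosine against the query; answer or decline.

    Descending score order, ties broken by original pair order.  The best
    answer is returned iff its score reaches `threshold`; an empty or fully
    out-of-vocabulary query scores 0 everywhere and yields no_answer.
    """
    qvec = kb.vectorize(query)
    scores = kb.question_vectors @ qvec
    order = sorted(range(len(kb.pairs)), key=lambda i: (-scores[i], i))
    ranked = tuple((kb.pairs[i], float(scores[i])) for i in order[:top_n])
    top_score = ranked[0][1] if ranked else 0.0
    if top_score >= threshold:
        return AnswerResult(
            status="answered", answer=ranked[0][0].answer, score=top_score, ranked=ranked
        )
    return AnswerResult(status="no_answer", answer=None, score=top_score, ranked=ranked)


def load_qa_pairs(source: Union[str, IO[str]], fmt: Optional[str] = None) -> list[QAPair]:
    """Read Q&A pairs from TSV (question<TAB>answer[<TAB>source]) or JSON."""
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "")
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
        name = str(source)
    if fmt is None:
        fmt = "json" if name.endswith(".json") or text.lstrip().startswith("[") else "tsv"
    if fmt == "json":
        doc = json.loads(text)
        return [
            QAPair(
                question=entry["question"],
                answer=entry["answer"],
                source=entry.get("source", ""),
            )
            for entry in doc
        ]
    pairs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise DomainError(f"line {lineno}: expected question<TAB>answer")
        pairs.append(
            QAPair(
                question=parts[0],
                answer=parts[1],
                source=parts[2] if len(parts) > 2 else "",
            )
        )
    return pairs


def save_qa_pairs(pairs: Iterable[QAPair], target: Union[str, IO[str]]) -> None:
    """Write pairs as TSV, the format `load_qa_pairs` reads back."""
    lines = "".join(f"{p.question}\t{p.answer}\t{p.source}\n" for p in pairs)
    if hasattr(target, "write"):
        target.write(lines)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(lines)
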