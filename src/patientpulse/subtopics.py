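"""Tokenization, subtopic dictionary matching, term selection and the
Gini-index discrimination measure.

A term's discriminative power across ``k`` document classes is measured by
the Gini index ``G(w) = sum_i p_i(w)**2``, where ``p_i(w)`` is the
conditional probability that a document belongs to class ``i`` given that
it contains ``w``.  ``G`` ranges from ``1/k`` (the term is spread uniformly
over classes, uninformative) to ``1`` (the term occurs in a single class,
perfectly discriminative).

Matching is token-exact and unstemmed: dictionary entries mix stems and
full words, so stemming would change their meaning ("bleeding" does not
match the entry "bleed").  Two-word entries such as "health care" are
matched as adjacent token bigrams.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, SubtopicDictionary

_STRIP = string.punctuation + "‘’“”–—…"
# keep internal hyphens/apostrophes; strip only leading/trailing punctuation
_KEEP_INTERNAL = set("-'’")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip leading/trailing punctuation.

    Internal hyphens and apostrophes are preserved ("can't" stays one
    token).  Deterministic; empty text gives an empty list.
    """
    tokens = []
    for raw in text.lower().split():
        tok = raw.strip(_STRIP)
        if tok:
            tokens.append(tok)
    return tokens


@dataclass
class TermFrequencyTable:
    """Occurrence counts per (subtopic, term) plus per-post hit lists.

    ``counts[subtopic][term]`` is the total number of occurrences across
    the corpus (a term appearing twice in one post counts twice).
    ``post_hits[post_id]`` lists every (subtopic, term) hit in that post.
    """

    counts: dict[str, Counter]
    post_hits: dict[str, list[tuple[str, str]]]

    def total(self, term: str) -> int:
        return sum(c[term] for c in self.counts.values())

    def flat_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.counts.values():
            for term, n in c.items():
                out[term] = out.get(term, 0) + n
        return out


def term_frequencies(corpus: Corpus,
                     dictionaries: Sequence[SubtopicDictionary]) -> TermFrequencyTable:
    """Count dictionary-term occurrences in a corpus.

    Single-word entries are matched as exact lowercase tokens; two-word
    entries as adjacent token bigrams.  Dictionaries must be disjoint.
    """
    seen: dict[str, str] = {}
    for d in dictionaries:
        for term in d.entries:
            if term in seen:
                raise ValueError(
                    f"term {term!r} appears in both {seen[term]!r} and {d.name!r}"
                )
            seen[term] = d.name

    unigrams = {t: d.name for d in dictionaries for t in d.entries if " " not in t}
    bigrams = {t: d.name for d in dictionaries for t in d.entries if " " in t}

    counts: dict[str, Counter] = {d.name: Counter() for d in dictionaries}
    post_hits: dict[str, list[tuple[str, str]]] = {}
    for post in corpus:
        hits: list[tuple[str, str]] = []
        toks = tokenize(post.text)
        for tok in toks:
            if tok in unigrams:
                hits.append((unigrams[tok], tok))
        for a, b in zip(toks, toks[1:]):
            pair = f"{a} {b}"
            if pair in bigrams:
                hits.append((bigrams[pair], pair))
        for sub, term in hits:
            counts[sub][term] += 1
        post_hits[post.post_id] = hits
    return TermFrequencyTable(counts=counts, post_hits=post_hits)


def select_terms(table: TermFrequencyTable, min_count: int = 50) -> list[str]:
    """Terms whose corpus-wide count is at least ``min_count``, sorted by
    descending count (ties alphabetical)."""
    flat = table.flat_counts()
    kept = [(t, n) for t, n in flat.items() if n >= min_count]
    kept.sort(key=lambda tn: (-tn[1], tn[0]))
    return [t for t, _ in kept]


def class_conditional_probabilities(labels: Mapping[str, int],
                                    contains: Mapping[str, bool] | set,
                                    w: str, k: int) -> np.ndarray:
    """p_i(w): probability that a post belongs to class i given it contains w.

    Parameters
    ----------
    labels : map post_id -> class index in 0..k-1
    contains : set of post_ids containing w (or map post_id -> bool)
    """
    if isinstance(contains, Mapping):
        containing = {pid for pid, has in contains.items() if has}
    else:
        containing = set(contains)
    containing &= set(labels)
    if not containing:
        raise ValueError(f"term {w!r} occurs in no labeled post; p_i undefined")
    counts = np.zeros(k)
    for pid in containing:
        ci = labels[pid]
        if not (0 <= ci < k):
            raise ValueError(f"label {ci} of post {pid} outside 0..{k - 1}")
        counts[ci] += 1
    return counts / counts.sum()


@dataclass(frozen=True)
class GiniResult:
    term: str
    k: int
    p: tuple[float, ...]
    G: float


def gini_index(p: Sequence[float]) -> float:
    """G = sum(p_i**2) for a class-conditional probability vector.

    Lies in [1/k, 1]: 1/k at the uniform vector, 1 when a single class
    carries all the mass.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) < 1:
        raise ValueError("p must be a nonempty 1-D probability vector")
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValueError("probabilities must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    return float(np.sum(p ** 2))


def term_gini(labels: Mapping[str, int], contains: set, w: str, k: int) -> GiniResult:
    """Convenience wrapper: conditional probabilities plus Gini index."""
    p = class_conditional_probabilities(labels, contains, w, k)
    return GiniResult(term=w, k=k, p=tuple(p.tolist()), G=gini_index(p))
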