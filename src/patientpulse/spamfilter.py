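"""Spam-account heuristics: duplicate-post detection and prolific-author audit.

Accounts that repost news or advertisements tend to emit many duplicate
messages, so the first heuristic counts, per author, posts whose
normalized text (lowercased, punctuation stripped, whitespace collapsed)
repeats an earlier post by the same author.  Duplicate means exact match
of normalized text — near-duplicate edit-distance matching is deliberately
not used, keeping the filter auditable.

The second heuristic ranks the most prolific authors for human review;
deciding whether a prolific account belongs to a patient remains an
expert judgement, not an automatic classification.
"""

from __future__ import annotations

import logging
import string
from collections import Counter
from dataclasses import dataclass

from .corpus_io import Corpus

logger = logging.getLogger(__name__)

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)

#: Default duplicate tolerance: one repeated post (a single repost) is
#: tolerated; more duplicates flag the account.
DEFAULT_MAX_DUPLICATES = 1


def normalize_text(text: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return " ".join(text.lower().translate(_PUNCT_TABLE).split())


@dataclass(frozen=True)
class AuthorDuplicates:
    author_id: str
    n_posts: int
    n_duplicate_posts: int  # posts repeating an earlier normalized text
    max_clone_size: int     # largest group of identical posts


@dataclass
class DuplicateReport:
    """Per-author duplicate statistics covering every author with >= 1 post."""

    authors: dict[str, AuthorDuplicates]

    def __getitem__(self, author_id: str) -> AuthorDuplicates:
        return self.authors[author_id]

    def __len__(self) -> int:
        return len(self.authors)


def duplicate_counts(corpus: Corpus) -> DuplicateReport:
    """Count duplicate posts per author over the whole corpus.

    A post is a duplicate when its normalized text equals an earlier post
    by the same author.
    """
    texts: dict[str, Counter] = {}
    n_posts: Counter = Counter()
    for post in corpus:
        n_posts[post.author_id] += 1
        texts.setdefault(post.author_id, Counter())[normalize_text(post.text)] += 1
    authors = {}
    for author, counter in texts.items():
        dups = sum(c - 1 for c in counter.values())
        authors[author] = AuthorDuplicates(
            author_id=author,
            n_posts=n_posts[author],
            n_duplicate_posts=dups,
            max_clone_size=max(counter.values()),
        )
    return DuplicateReport(authors=authors)


def flag_spam_accounts(report: DuplicateReport,
                       max_duplicates: int = DEFAULT_MAX_DUPLICATES) -> set[str]:
    """Authors with more than ``max_duplicates`` duplicate posts."""
    if max_duplicates < 0:
        raise ValueError("max_duplicates must be nonnegative")
    return {
        a.author_id for a in report.authors.values()
        if a.n_duplicate_posts > max_duplicates
    }


def top_authors(corpus: Corpus, k: int) -> list[tuple[str, int]]:
    """The ``k`` most prolific authors, for human review.

    Descending by post count; ties broken lexicographically by author id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = Counter(p.author_id for p in corpus)
    ranked = sorted(counts.items(), key=lambda ac: (-ac[1], ac[0]))
    return ranked[:k]


def filter_corpus(corpus: Corpus, flagged: set[str]) -> Corpus:
    """Remove every post by a flagged author, preserving order."""
    kept = [p for p in corpus if p.author_id not in flagged]
    removed = len(corpus) - len(kept)
    logger.info("filter_corpus: removed %d of %d posts (%d flagged accounts)",
                removed, len(corpus), len(flagged))
    return Corpus(posts=kept, date_range=corpus.date_range if kept else None)
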