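"""Lexicon-based 3-class sentiment scoring and daily time-series aggregation.

Each post is scored by counting tokens found in the positive and negative
word lists; the label is the sign of the difference, so a tie or a text
with no lexicon words is neutral (0).  This is a transparent stand-in for
heavier subjectivity classifiers — the lexicon is pluggable, any plain
word list can be dropped in.  Negation ("not better") is deliberately not
handled in this version.

For association analysis, posts are aggregated into daily series over the
full corpus date range: per-day mention counts of a target term, the mean
label of the mentioning posts, and corpus-wide positive/negative shares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import Corpus, SentimentLexicon
from .subtopics import tokenize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SentimentScore:
    post_id: str
    n_positive_hits: int
    n_negative_hits: int
    label: int  # sign(n_positive_hits - n_negative_hits): -1, 0 or 1


def score_post(text: str, lexicon: SentimentLexicon,
               post_id: str = "") -> SentimentScore:
    """Score one text: label = sign(#positive hits − #negative hits)."""
    npos = nneg = 0
    for tok in tokenize(text):
        if tok in lexicon.positive:
            npos += 1
        elif tok in lexicon.negative:
            nneg += 1
    return SentimentScore(post_id=post_id, n_positive_hits=npos,
                          n_negative_hits=nneg,
                          label=int(np.sign(npos - nneg)))


def classify_corpus(corpus: Corpus, lexicon: SentimentLexicon) -> list[SentimentScore]:
    """Score every post; logs the resulting positive/neutral/negative mix."""
    scores = [score_post(p.text, lexicon, post_id=p.post_id) for p in corpus]
    if scores:
        labels = np.array([s.label for s in scores])
        n = len(labels)
        logger.info(
            "sentiment mix over %d posts: %.1f%% positive, %.1f%% neutral, %.1f%% negative",
            n, 100 * np.mean(labels == 1), 100 * np.mean(labels == 0),
            100 * np.mean(labels == -1),
        )
    return scores


@dataclass
class DailySeries:
    """Per-calendar-day mention counts and mean sentiment for one term.

    Covers every day of the corpus date range; days without mentions have
    ``mentions = 0`` and ``sentiment = 0``.
    """

    term: str
    dates: pd.DatetimeIndex
    mentions: np.ndarray
    sentiment: np.ndarray

    def __len__(self) -> int:
        return len(self.dates)


def _full_day_index(corpus: Corpus) -> pd.DatetimeIndex:
    if corpus.date_range is None:
        return pd.DatetimeIndex([], tz="UTC")
    lo, hi = corpus.date_range
    return pd.date_range(lo.date(), hi.date(), freq="D", tz="UTC")


def daily_series(corpus: Corpus, scores: list, term: str) -> DailySeries:
    """Daily mention count and mean label of posts containing ``term``.

    ``scores`` must be aligned to the corpus (one score per post, in
    order).  Multi-word terms are matched as adjacent token bigrams.
    """
    if not term or not term.strip():
        raise ValueError("term must be nonempty")
    term = " ".join(term.lower().split())
    if len(scores) != len(corpus):
        raise ValueError("scores not aligned to corpus")

    days = _full_day_index(corpus)
    mentions = np.zeros(len(days), dtype=int)
    label_sum = np.zeros(len(days), dtype=float)
    day_pos = {d: i for i, d in enumerate(days)}
    for post, score in zip(corpus, scores):
        toks = tokenize(post.text)
        if " " in term:
            hit = any(f"{a} {b}" == term for a, b in zip(toks, toks[1:]))
        else:
            hit = term in toks
        if hit:
            i = day_pos[pd.Timestamp(post.timestamp.date(), tz="UTC")]
            mentions[i] += 1
            label_sum[i] += score.label
    sentiment = np.divide(label_sum, mentions, out=np.zeros(len(days)),
                          where=mentions > 0)
    return DailySeries(term=term, dates=days, mentions=mentions, sentiment=sentiment)


def daily_sentiment_shares(corpus: Corpus, scores: list) -> pd.DataFrame:
    """Per-day share of positive and negative posts among all posts that day.

    Returns a DataFrame indexed by calendar day with columns ``n_posts``,
    ``pos_share`` and ``neg_share`` (0 on empty days).  These are the
    response series for term–sentiment association tests.
    """
    if len(scores) != len(corpus):
        raise ValueError("scores not aligned to corpus")
    days = _full_day_index(corpus)
    n = np.zeros(len(days), dtype=int)
    npos = np.zeros(len(days), dtype=int)
    nneg = np.zeros(len(days), dtype=int)
    day_pos = {d: i for i, d in enumerate(days)}
    for post, score in zip(corpus, scores):
        i = day_pos[pd.Timestamp(post.timestamp.date(), tz="UTC")]
        n[i] += 1
        if score.label == 1:
            npos[i] += 1
        elif score.label == -1:
            nneg[i] += 1
    pos_share = np.divide(npos, n, out=np.zeros(len(days)), where=n > 0)
    neg_share = np.divide(nneg, n, out=np.zeros(len(days)), where=n > 0)
    return pd.DataFrame(
        {"n_posts": n, "pos_share": pos_share, "neg_share": neg_share}, index=days
    )
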