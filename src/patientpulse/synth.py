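"""Seeded synthetic-data generator with known ground truth.

Emulates the statistical structure the pipeline assumes in a scraped
patient-community corpus: accounts with heterogeneous (Poisson) posting
rates, a spam subpopulation that reposts identical advertisement texts,
posts seeded with subtopic-dictionary terms, post-level sentiment
polarity expressed through lexicon words, and an optional lagged coupling
in which the daily mention count of one drug term shifts the sentiment
mix of the following day's posts — so Granger structure is recoverable by
construction.

Post texts are assembled from a closed vocabulary (dictionary terms,
lexicon terms, neutral filler words and a unique serial token), which
makes every downstream stage exactly checkable against the returned
:class:`GroundTruth`.  No attempt is made to mimic natural-language
fluency or platform metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

import numpy as np

from .corpus_io import Corpus, Post, SubtopicDictionary, packaged_dictionaries, packaged_lexicon

#: Neutral filler vocabulary: disjoint from every packaged dictionary entry,
#: every lexicon word, and the word pieces of the two-word entries.
FILLER_WORDS = (
    "today", "really", "about", "with", "just", "have", "been", "week",
    "month", "going", "still", "some", "that", "this", "then", "when",
    "from", "they", "again", "everyone", "anyone", "because", "thing",
    "while", "maybe", "year", "people", "share", "story", "update",
)

_SPAM_BASE = ("breaking", "news", "click", "here", "offer")

_DEFAULT_RANGE = (date(2011, 10, 1), date(2015, 8, 31))


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    Defaults describe a scaled-down patient community: 100 accounts
    posting at Poisson rate 20 over the October 2011 – August 2015
    window, a 10% spam subpopulation, each dictionary seeded into 30% of
    genuine posts, and a positive/neutral/negative sentiment mix of
    36/27/37 (the mix reported for the drug-opinion posts this corpus
    emulates).  ``coupling_beta`` > 0 makes high mention days of
    ``coupled_term`` shift the next ``coupling_lag`` day's mix toward
    positive (and low days toward negative) on a log-odds scale.
    """

    n_accounts: int = 100
    spam_fraction: float = 0.1
    posts_per_account_mean: float = 20.0
    date_range: tuple[date, date] = _DEFAULT_RANGE
    subtopic_term_rate: float = 0.3
    sentiment_mix: tuple[float, float, float] = (0.36, 0.27, 0.37)  # pos, neu, neg
    coupling_beta: float = 0.0
    coupling_lag: int = 1
    coupled_term: str = "infliximab"
    coupled_term_rate: float = 0.2
    polarity_noise: float = 0.0
    facebook_share: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_accounts < 1:
            raise ValueError("n_accounts must be positive")
        if not (0 <= self.spam_fraction < 1):
            raise ValueError("spam_fraction must lie in [0, 1)")
        if self.posts_per_account_mean <= 0:
            raise ValueError("posts_per_account_mean must be positive")
        start, end = self.date_range
        if start > end:
            raise ValueError("empty date_range")
        for p in (self.subtopic_term_rate, self.coupled_term_rate,
                  self.polarity_noise, self.facebook_share):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.sentiment_mix) - 1.0) > 1e-9:
            raise ValueError("sentiment_mix must sum to 1")
        if any(p < 0 for p in self.sentiment_mix):
            raise ValueError("sentiment_mix entries must be nonnegative")
        if self.coupling_lag < 1:
            raise ValueError("coupling_lag must be a positive integer")
        if not math.isfinite(self.coupling_beta):
            raise ValueError("coupling_beta must be finite")


@dataclass
class GroundTruth:
    """Generator-side labels for every synthetic post."""

    spam_accounts: set[str]
    post_sentiment: dict[str, int]          # post_id -> -1/0/1
    post_subtopics: dict[str, set[str]]     # post_id -> subtopic names
    term_counts: dict[str, int]             # injected occurrences per term
    daily_mentions: dict[str, int] = field(default_factory=dict)  # ISO day -> posts mentioning coupled term

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "spam_accounts": sorted(self.spam_accounts),
            "post_sentiment": self.post_sentiment,
            "post_subtopics": {k: sorted(v) for k, v in self.post_subtopics.items()},
            "term_counts": self.term_counts,
            "daily_mentions": self.daily_mentions,
        }, indent=1), encoding="utf-8")


def generate_corpus(config: GeneratorConfig,
                    dictionaries: dict[str, SubtopicDictionary] | None = None,
                    ) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus plus its ground truth; identical seed, identical output.

    Guarantees by construction: every spam account emits at least one
    exact-duplicate pair; non-spam texts are pairwise distinct (each
    carries a unique serial token); a post labeled positive (negative)
    contains strictly more positive (negative) lexicon words than the
    opposite polarity unless polarity noise flips its wording; a
    subtopic-labeled post contains at least one term of that dictionary.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dicts = dictionaries if dictionaries is not None else packaged_dictionaries()
    lexicon = packaged_lexicon()
    pos_words = sorted(lexicon.positive)
    neg_words = sorted(lexicon.negative)

    start, end = config.date_range
    n_days = (end - start).days + 1

    n_spam = int(round(config.spam_fraction * config.n_accounts))
    account_ids = [f"user{i:05d}" for i in range(config.n_accounts)]
    spam_accounts = set(rng.choice(account_ids, size=n_spam, replace=False).tolist())

    # phase A: per-post day / coupled-term presence, so daily mention
    # counts exist before sentiment labels are drawn
    plan: list[dict] = []
    serial = 0
    for acct in account_ids:
        is_spam = acct in spam_accounts
        n_posts = int(rng.poisson(config.posts_per_account_mean))
        n_posts = max(n_posts, 2 if is_spam else 1)
        for k in range(n_posts):
            day = int(rng.integers(0, n_days))
            has_coupled = (not is_spam) and bool(rng.random() < config.coupled_term_rate)
            plan.append({"acct": acct, "spam": is_spam, "day": day,
                         "coupled": has_coupled, "serial": serial,
                         "acct_idx": k})
            serial += 1

    mentions = np.zeros(n_days, dtype=int)
    for item in plan:
        if item["coupled"]:
            mentions[item["day"]] += 1
    sd = mentions.std()
    z = (mentions - mentions.mean()) / sd if sd > 0 else np.zeros(n_days)

    p_pos, p_neu, p_neg = config.sentiment_mix
    lag = config.coupling_lag
    beta = config.coupling_beta

    posts: list[Post] = []
    gt = GroundTruth(spam_accounts=set(spam_accounts), post_sentiment={},
                     post_subtopics={}, term_counts={},
                     daily_mentions={
                         (start + timedelta(days=d)).isoformat(): int(mentions[d])
                         for d in range(n_days)
                     })

    for item in plan:
        pid = f"post{item['serial']:07d}"
        day = item["day"]
        ts = datetime.combine(start + timedelta(days=day),
                              datetime.min.time(), tzinfo=timezone.utc)
        ts += timedelta(seconds=int(rng.integers(0, 86400)))
        platform = "facebook" if rng.random() < config.facebook_share else "twitter"

        if item["spam"]:
            # first two posts are always the bare advertisement, guaranteeing
            # at least one exact-duplicate pair per spam account
            base = " ".join(_SPAM_BASE) + f" {item['acct']}"
            variant = item["acct_idx"] >= 2 and rng.random() < 0.4
            text = base + f" ref{item['serial']:07d}" if variant else base
            gt.post_sentiment[pid] = 0
            gt.post_subtopics[pid] = set()
            posts.append(Post(pid, item["acct"], platform, ts, text))
            continue

        # sentiment label, shifted on the log scale by lagged mentions
        if beta != 0.0 and day - lag >= 0:
            shift = beta * z[day - lag]
            wts = np.array([p_pos * math.exp(shift), p_neu,
                            p_neg * math.exp(-shift)])
        else:
            wts = np.array([p_pos, p_neu, p_neg])
        wts = wts / wts.sum()
        label = int(rng.choice([1, 0, -1], p=wts))
        gt.post_sentiment[pid] = label

        # subtopic term injections
        chunks: list[str] = []
        subs: set[str] = set()
        for name, d in dicts.items():
            if rng.random() < config.subtopic_term_rate:
                # the coupled term enters only via its own channel, so the
                # daily-mentions ground truth stays exact
                pool = [t for t in d.entries if t != config.coupled_term]
                if not pool:
                    continue
                term = pool[int(rng.integers(0, len(pool)))]
                chunks.append(term)
                subs.add(name)
                gt.term_counts[term] = gt.term_counts.get(term, 0) + 1
        if item["coupled"]:
            chunks.append(config.coupled_term)
            subs.add("treatments")
            gt.term_counts[config.coupled_term] = \
                gt.term_counts.get(config.coupled_term, 0) + 1
        gt.post_subtopics[pid] = subs

        # polarity wording; noise renders the words of a different label
        render = label
        if config.polarity_noise > 0 and rng.random() < config.polarity_noise:
            others = [l for l in (1, 0, -1) if l != label]
            render = int(others[int(rng.integers(0, 2))])
        if render == 1:
            for _ in range(int(rng.integers(1, 3))):
                chunks.append(pos_words[int(rng.integers(0, len(pos_words)))])
        elif render == -1:
            for _ in range(int(rng.integers(1, 3))):
                chunks.append(neg_words[int(rng.integers(0, len(neg_words)))])
        elif rng.random() < 0.25:  # occasional explicit tie, still neutral
            chunks.append(pos_words[int(rng.integers(0, len(pos_words)))])
            chunks.append(neg_words[int(rng.integers(0, len(neg_words)))])

        n_fill = int(rng.integers(3, 7))
        chunks.extend(FILLER_WORDS[int(i)] for i in
                      rng.integers(0, len(FILLER_WORDS), size=n_fill))
        order = rng.permutation(len(chunks))
        words = [chunks[i] for i in order]  # two-word terms move as units
        words.append(f"ref{item['serial']:07d}")  # guarantees distinct texts
        posts.append(Post(pid, item["acct"], platform, ts, " ".join(words)))

    posts.sort(key=lambda p: (p.timestamp, p.post_id))
    lo = datetime.combine(start, datetime.min.time(), tzinfo=timezone.utc)
    hi = datetime.combine(end, datetime.max.time(), tzinfo=timezone.utc)
    return Corpus(posts=posts, date_range=(lo, hi)), gt


def generate_coupled_series(n: int, beta: float, lag: int,
                            noise_sd: float = 1.0, seed: int = 0,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """White-noise predictor x (sd 1) and response y_t = beta*x_{t-lag} + eps_t.

    eps ~ Normal(0, noise_sd^2); the first ``lag`` values of y are pure
    noise.  A testbed with known causal structure for the Granger test.
    """
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    if n <= 10 * lag:
        raise ValueError(f"need n > 10*lag (= {10 * lag}), got {n}")
    if not (math.isfinite(beta) and math.isfinite(noise_sd)):
        raise ValueError("beta and noise_sd must be finite")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    eps = noise_sd * rng.standard_normal(n)
    y = eps.copy()
    y[lag:] += beta * x[:-lag]
    return x, y


def generate_rating_pairs(cell_counts, seed: int = 0,
                          scores: tuple[int, ...] = (-1, 0, 1),
                          ) -> list[tuple[int, int]]:
    """Expand a k×k contingency table into a shuffled list of rating pairs.

    The cross-tabulation of the returned pairs equals ``cell_counts``
    exactly; order is shuffled by ``seed``.
    """
    m = np.asarray(cell_counts)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("cell_counts must be a square matrix")
    if m.shape[0] != len(scores):
        raise ValueError("matrix size must match the score scale")
    if not np.issubdtype(m.dtype, np.integer):
        if not np.all(m == np.floor(m)):
            raise ValueError("cell counts must be integers")
        m = m.astype(int)
    if np.any(m < 0):
        raise ValueError("cell counts must be nonnegative")
    pairs = [(scores[i], scores[j])
             for i in range(m.shape[0]) for j in range(m.shape[1])
             for _ in range(int(m[i, j]))]
    rng = np.random.default_rng(seed)
    rng.shuffle(pairs)
    return [tuple(p) for p in pairs]
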