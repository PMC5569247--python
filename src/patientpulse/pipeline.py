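"""End-to-end orchestration: spam filtering → subtopic tagging → term
selection → sentiment scoring → Granger term ranking, with a JSON report.

Every stage logs its input/output counts so the funnel from raw corpus to
analyzed posts is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import corpus_io, spamfilter, subtopics, sentiment, association
from .corpus_io import Corpus, SentimentLexicon, SubtopicDictionary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Paths left as None fall back to the packaged dictionaries/lexicon.
    """

    corpus_path: str | None = None
    dictionary_paths: dict[str, str] | None = None
    lexicon_positive_path: str | None = None
    lexicon_negative_path: str | None = None
    spam_max_duplicates: int = spamfilter.DEFAULT_MAX_DUPLICATES
    term_min_count: int = 50
    granger_lag: int = 1
    granger_alpha: float = 0.05
    candidate_terms: list[str] = field(
        default_factory=lambda: ["adalimumab", "azathioprine", "infliximab"])
    kappa_scheme: str = "quadratic"
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.spam_max_duplicates < 0:
            raise ValueError("spam_max_duplicates must be nonnegative")
        if self.term_min_count < 0:
            raise ValueError("term_min_count must be nonnegative")
        if self.granger_lag < 1:
            raise ValueError("granger_lag must be positive")
        if not (0 < self.granger_alpha < 1):
            raise ValueError("granger_alpha must lie in (0, 1)")
        if self.corpus_path is not None and not Path(self.corpus_path).exists():
            raise FileNotFoundError(f"corpus not found: {self.corpus_path}")


@dataclass
class PipelineReport:
    """Machine-readable result of one pipeline run."""

    seed: int
    n_posts_in: int
    n_posts_kept: int
    flagged_accounts: list[str]
    selected_terms: list[str]
    term_counts: dict[str, int]
    sentiment_proportions: dict[str, float]
    term_ranking: list[dict]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    def to_text(self) -> str:
        lines = [
            f"posts in: {self.n_posts_in}, kept after spam filter: {self.n_posts_kept}",
            f"flagged accounts: {len(self.flagged_accounts)}",
            "sentiment mix: " + ", ".join(
                f"{k} {100 * v:.1f}%" for k, v in self.sentiment_proportions.items()),
            f"terms at or above threshold: {len(self.selected_terms)}",
            "term ranking (min p-value across polarities):",
        ]
        for row in self.term_ranking:
            flag = " *" if row["significant"] else ""
            lines.append(
                f"  {row['term']}: p_pos={row['p_positive']:.4g} "
                f"p_neg={row['p_negative']:.4g}{flag}")
        return "\n".join(lines)


def run_pipeline(config: PipelineConfig,
                 corpus: Corpus | None = None,
                 dictionaries: dict[str, SubtopicDictionary] | None = None,
                 lexicon: SentimentLexicon | None = None) -> PipelineReport:
    """Run the full analysis on a corpus.

    ``corpus`` may be passed in memory; otherwise ``config.corpus_path``
    is read.  Intermediate artifacts and the report are written to
    ``config.output_dir`` when set.  Deterministic given the corpus and
    configuration.
    """
    config.validate()

    def stage(name):
        logger.info("pipeline stage: %s", name)

    stage("load")
    if corpus is None:
        if config.corpus_path is None:
            raise ValueError("no corpus given: set corpus_path or pass corpus")
        corpus = corpus_io.read_posts(config.corpus_path)
    if dictionaries is None:
        if config.dictionary_paths:
            dictionaries = {
                name: corpus_io.load_dictionary(p, name=name)
                for name, p in config.dictionary_paths.items()}
        else:
            dictionaries = corpus_io.packaged_dictionaries()
    if lexicon is None:
        if config.lexicon_positive_path and config.lexicon_negative_path:
            lexicon = corpus_io.load_lexicon(
                config.lexicon_positive_path, config.lexicon_negative_path)
        else:
            lexicon = corpus_io.packaged_lexicon()

    stage("spam-filter")
    report = spamfilter.duplicate_counts(corpus)
    flagged = spamfilter.flag_spam_accounts(report, config.spam_max_duplicates)
    kept = spamfilter.filter_corpus(corpus, flagged)

    stage("subtopics")
    freqs = subtopics.term_frequencies(kept, list(dictionaries.values()))
    selected = subtopics.select_terms(freqs, min_count=config.term_min_count)

    stage("sentiment")
    scores = sentiment.classify_corpus(kept, lexicon)
    labels = np.array([s.label for s in scores]) if scores else np.array([])
    props = {
        "positive": float(np.mean(labels == 1)) if len(labels) else 0.0,
        "neutral": float(np.mean(labels == 0)) if len(labels) else 0.0,
        "negative": float(np.mean(labels == -1)) if len(labels) else 0.0,
    }

    stage("granger")
    ranking = association.rank_terms(
        kept, scores, config.candidate_terms,
        lag=config.granger_lag, alpha=config.granger_alpha)

    result = PipelineReport(
        seed=config.seed,
        n_posts_in=len(corpus),
        n_posts_kept=len(kept),
        flagged_accounts=sorted(flagged),
        selected_terms=selected,
        term_counts=freqs.flat_counts(),
        sentiment_proportions=props,
        term_ranking=[{
            "term": r.term,
            "p_positive": r.positive.p_value,
            "p_negative": r.negative.p_value,
            "F_positive": r.positive.F,
            "F_negative": r.negative.F,
            "lag": r.positive.lag,
            "significant": r.significant,
            "degenerate": r.degenerate,
        } for r in ranking],
    )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(result.to_json(), encoding="utf-8")
        (out / "report.txt").write_text(result.to_text() + "\n", encoding="utf-8")
        corpus_io.write_posts(kept, out / "filtered_corpus.jsonl")
    return result
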