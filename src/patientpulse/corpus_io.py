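"""Domain types and I/O for social-media corpora, word lists, and rating files.

The unit of analysis is a :class:`Post` — one public message from a patient
community page, carrying an author handle, platform, UTC timestamp and free
text.  A :class:`Corpus` is an ordered collection of posts together with the
calendar range it covers.  Subtopic dictionaries (curated word lists for
lifestyle, symptoms, treatments and side effects) and sentiment lexicons
(positive/negative word lists) are plain-text files, one term per line or
comma-separated.

Canonical on-disk corpus format is JSON Lines; CSV is supported with the
fixed column order ``post_id, author_id, platform, timestamp, text``.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

PLATFORMS = ("facebook", "twitter")
SUBTOPIC_NAMES = ("lifestyle", "symptoms", "treatments", "side_effects")

CSV_COLUMNS = ("post_id", "author_id", "platform", "timestamp", "text")


class CorpusFormatError(ValueError):
    """A corpus, dictionary or rating file violates its format contract."""


def _parse_timestamp(value: str) -> datetime:
    """Parse an ISO-8601 timestamp; naive values are taken as UTC."""
    ts = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


@dataclass(frozen=True)
class Post:
    """One social-media message.

    Attributes
    ----------
    post_id, author_id : str
        Opaque identifiers; ``post_id`` is unique within a corpus.
    platform : str
        ``"facebook"`` or ``"twitter"``.
    timestamp : datetime
        UTC timestamp of publication.
    text : str
        The message body.
    """

    post_id: str
    author_id: str
    platform: str
    timestamp: datetime
    text: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise CorpusFormatError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )


@dataclass
class Corpus:
    """Ordered collection of posts with the calendar range they span."""

    posts: list[Post]
    date_range: tuple[datetime, datetime] | None = None

    def __post_init__(self) -> None:
        ids = [p.post_id for p in self.posts]
        if len(ids) != len(set(ids)):
            raise CorpusFormatError("duplicate post_id in corpus")
        if self.date_range is None and self.posts:
            stamps = [p.timestamp for p in self.posts]
            self.date_range = (min(stamps), max(stamps))
        if self.date_range is not None:
            lo, hi = self.date_range
            for p in self.posts:
                if not (lo <= p.timestamp <= hi):
                    raise CorpusFormatError(
                        f"post {p.post_id} timestamp outside corpus date range"
                    )

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)


@dataclass(frozen=True)
class SubtopicDictionary:
    """Named word list used to tag posts with a subtopic.

    Entries are lowercase, unique and order-stable; multi-word entries
    contain exactly one internal space and are matched as token bigrams.
    """

    name: str
    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise CorpusFormatError(f"dictionary {self.name!r} is empty")
        seen = set()
        for e in self.entries:
            if e != e.lower() or e != e.strip():
                raise CorpusFormatError(f"entry {e!r} not normalized")
            if e.count(" ") > 1:
                raise CorpusFormatError(f"entry {e!r} has more than two words")
            if e in seen:
                raise CorpusFormatError(f"duplicate entry {e!r}")
            seen.add(e)


@dataclass(frozen=True)
class SentimentLexicon:
    """Positive/negative polarity word lists for lexicon sentiment scoring."""

    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positive or not self.negative:
            raise CorpusFormatError("both polarity lists must be nonempty")
        clash = self.positive & self.negative
        if clash:
            raise CorpusFormatError(
                f"terms in both polarity lists: {sorted(clash)[:5]}"
            )


def read_posts(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from a JSON Lines or CSV file.

    Records are returned in file order.  A malformed record (missing field,
    unparseable timestamp) raises :class:`CorpusFormatError` naming the
    record number; nothing is silently dropped.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")

    posts: list[Post] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"record {lineno}: invalid JSON: {exc}")
                posts.append(_record_to_post(rec, lineno))
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise CorpusFormatError(f"CSV header missing columns {sorted(missing)}")
            for lineno, rec in enumerate(reader, start=2):
                posts.append(_record_to_post(rec, lineno))

    if not posts:
        logger.warning("read_posts: %s contains no records", path)
        return Corpus(posts=[])
    return Corpus(posts=posts)


def _record_to_post(rec: dict, lineno: int) -> Post:
    for key in CSV_COLUMNS:
        if key not in rec or rec[key] is None or rec[key] == "":
            raise CorpusFormatError(f"record {lineno}: missing field {key!r}")
    try:
        ts = _parse_timestamp(rec["timestamp"])
    except (ValueError, TypeError) as exc:
        raise CorpusFormatError(f"record {lineno}: bad timestamp: {exc}")
    try:
        return Post(
            post_id=str(rec["post_id"]),
            author_id=str(rec["author_id"]),
            platform=str(rec["platform"]),
            timestamp=ts,
            text=str(rec["text"]),
        )
    except CorpusFormatError as exc:
        raise CorpusFormatError(f"record {lineno}: {exc}")


def write_posts(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus as JSON Lines (canonical) or CSV; inverse of read_posts."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for p in corpus:
                fh.write(json.dumps({
                    "post_id": p.post_id,
                    "author_id": p.author_id,
                    "platform": p.platform,
                    "timestamp": p.timestamp.isoformat(),
                    "text": p.text,
                }, ensure_ascii=False) + "\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for p in corpus:
                writer.writerow(
                    [p.post_id, p.author_id, p.platform, p.timestamp.isoformat(), p.text]
                )
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def _parse_term_lines(raw: str) -> list[str]:
    terms: list[str] = []
    seen: set[str] = set()
    for line in raw.splitlines():
        for piece in line.split(","):
            term = " ".join(piece.lower().split())
            if term and term not in seen:
                seen.add(term)
                terms.append(term)
    return terms


def load_dictionary(path: str | Path, name: str | None = None) -> SubtopicDictionary:
    """Load a subtopic dictionary from a newline- or comma-separated word list.

    Entries are lowercased, whitespace-normalized and deduplicated, keeping
    first-occurrence order.  An empty file is an error.
    """
    path = Path(path)
    terms = _parse_term_lines(path.read_text(encoding="utf-8"))
    if not terms:
        raise CorpusFormatError(f"dictionary file {path} is empty")
    return SubtopicDictionary(name=name or path.stem, entries=tuple(terms))


def load_lexicon(positive_path: str | Path, negative_path: str | Path) -> SentimentLexicon:
    """Load a sentiment lexicon from two plain-text word lists."""
    pos = _parse_term_lines(Path(positive_path).read_text(encoding="utf-8"))
    neg = _parse_term_lines(Path(negative_path).read_text(encoding="utf-8"))
    return SentimentLexicon(positive=frozenset(pos), negative=frozenset(neg))


def _data_text(filename: str) -> str:
    return resources.files("patientpulse.data").joinpath(filename).read_text("utf-8")


def packaged_dictionaries() -> dict[str, SubtopicDictionary]:
    """The four packaged subtopic dictionaries (lifestyle, symptoms,
    treatments, side_effects)."""
    out = {}
    for name in SUBTOPIC_NAMES:
        terms = _parse_term_lines(_data_text(f"{name}.txt"))
        out[name] = SubtopicDictionary(name=name, entries=tuple(terms))
    return out


def packaged_lexicon() -> SentimentLexicon:
    """The packaged default polarity lexicon (pluggable; any plain word
    lists, e.g. an external subjectivity-clue lexicon, can replace it)."""
    return SentimentLexicon(
        positive=frozenset(_parse_term_lines(_data_text("lexicon_positive.txt"))),
        negative=frozenset(_parse_term_lines(_data_text("lexicon_negative.txt"))),
    )


def read_ratings(path_or_buffer: str | Path | io.TextIOBase,
                 scores: Sequence[int] = (-1, 0, 1)) -> list[tuple[int, int]]:
    """Read a two-column CSV of paired Likert ratings (rater_a, rater_b).

    Values must belong to ``scores``.  A header row is accepted and skipped.
    """
    if isinstance(path_or_buffer, (str, Path)):
        fh = open(path_or_buffer, encoding="utf-8", newline="")
        close = True
    else:
        fh, close = path_or_buffer, False
    try:
        pairs: list[tuple[int, int]] = []
        allowed = set(scores)
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            if lineno == 1 and not _is_int(row[0]):
                continue  # header
            if len(row) < 2:
                raise CorpusFormatError(f"ratings row {lineno}: need two columns")
            try:
                a, b = int(row[0]), int(row[1])
            except ValueError:
                raise CorpusFormatError(f"ratings row {lineno}: non-integer rating")
            if a not in allowed or b not in allowed:
                raise CorpusFormatError(
                    f"ratings row {lineno}: rating outside scale {sorted(allowed)}"
                )
            pairs.append((a, b))
        if not pairs:
            raise CorpusFormatError("ratings file contains no rating pairs")
        return pairs
    finally:
        if close:
            fh.close()


def write_ratings(pairs: Iterable[tuple[int, int]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rater_a", "rater_b"])
        for a, b in pairs:
            writer.writerow([a, b])


def packaged_ratings() -> list[tuple[int, int]]:
    """The packaged 261-pair expert rating fixture (gastroenterologist vs
    computer-science expert, 3-point Likert scale)."""
    return read_ratings(io.StringIO(_data_text("expert_ratings.csv")))


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False
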