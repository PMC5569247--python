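from datetime import datetime, timezone

import pytest

from patientpulse.corpus_io import Corpus, Post

EXPERT_CELLS = ((62, 17, 5), (22, 40, 16), (11, 13, 75))


def make_post(post_id="p1", author="a1", platform="facebook",
              when="2013-05-01T12:00:00+00:00", text="hello world"):
    return Post(post_id=post_id, author_id=author, platform=platform,
                timestamp=datetime.fromisoformat(when).astimezone(timezone.utc),
                text=text)


def make_corpus(texts_by_author, start_day="2013-05-01"):
    """Corpus with one post per (author, text), all on sequential days."""
    posts = []
    i = 0
    for author, texts in texts_by_author.items():
        for text in texts:
            day = 1 + (i % 27)
            posts.append(make_post(post_id=f"p{i}", author=author,
                                   when=f"2013-05-{day:02d}T10:00:00+00:00",
                                   text=text))
            i += 1
    return Corpus(posts=posts)


@pytest.fixture
def expert_matrix():
    from patientpulse.agreement import ConfusionMatrix
    return ConfusionMatrix(scores=(-1, 0, 1), cells=EXPERT_CELLS)
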