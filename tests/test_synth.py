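from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patientpulse import synth
from patientpulse.agreement import build_confusion_matrix
from patientpulse.spamfilter import duplicate_counts, flag_spam_accounts

SHORT_RANGE = (date(2013, 1, 1), date(2013, 6, 30))


def small_config(**kw):
    defaults = dict(n_accounts=40, spam_fraction=0.2, posts_per_account_mean=10,
                    date_range=SHORT_RANGE, seed=1)
    defaults.update(kw)
    return synth.GeneratorConfig(**defaults)


class TestGenerateCorpus:
    def test_same_seed_identical_output(self):
        c1, g1 = synth.generate_corpus(small_config(seed=7))
        c2, g2 = synth.generate_corpus(small_config(seed=7))
        assert c1.posts == c2.posts
        assert g1.post_sentiment == g2.post_sentiment
        c3, _ = synth.generate_corpus(small_config(seed=8))
        assert c3.posts != c1.posts

    def test_no_spam_means_no_duplicates(self):
        corpus, _ = synth.generate_corpus(small_config(spam_fraction=0.0))
        report = duplicate_counts(corpus)
        assert all(a.n_duplicate_posts == 0 for a in report.authors.values())

    def test_spam_accounts_recovered_exactly(self):
        config = synth.GeneratorConfig(n_accounts=50, spam_fraction=0.2,
                                       date_range=SHORT_RANGE, seed=1)
        corpus, truth = synth.generate_corpus(config)
        report = duplicate_counts(corpus)
        assert flag_spam_accounts(report, 1) == truth.spam_accounts

    def test_sentiment_words_match_labels(self):
        from patientpulse.corpus_io import packaged_lexicon
        from patientpulse.subtopics import tokenize
        lex = packaged_lexicon()
        corpus, truth = synth.generate_corpus(small_config())
        for post in corpus:
            toks = tokenize(post.text)
            npos = sum(t in lex.positive for t in toks)
            nneg = sum(t in lex.negative for t in toks)
            assert int(np.sign(npos - nneg)) == truth.post_sentiment[post.post_id]

    def test_subtopic_labels_backed_by_terms(self):
        from patientpulse.corpus_io import packaged_dictionaries
        from patientpulse.subtopics import term_frequencies
        corpus, truth = synth.generate_corpus(small_config())
        dicts = packaged_dictionaries()
        table = term_frequencies(corpus, list(dicts.values()))
        for post in corpus:
            hit_subs = {s for s, _ in table.post_hits[post.post_id]}
            assert truth.post_subtopics[post.post_id] <= hit_subs

    def test_sentiment_mix_converges(self):
        mix = (0.36, 0.27, 0.37)
        config = synth.GeneratorConfig(
            n_accounts=500, spam_fraction=0.0, posts_per_account_mean=20,
            date_range=SHORT_RANGE, sentiment_mix=mix, seed=3)
        _, truth = synth.generate_corpus(config)
        labels = np.array(list(truth.post_sentiment.values()))
        n = len(labels)
        assert n >= 9000
        for value, p in zip((1, 0, -1), mix):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(np.mean(labels == value) - p) < 3 * se

    def test_empty_date_range_is_error(self):
        with pytest.raises(ValueError, match="date_range"):
            synth.generate_corpus(small_config(
                date_range=(date(2014, 1, 1), date(2013, 1, 1))))

    def test_bad_mix_is_error(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(sentiment_mix=(0.5, 0.5, 0.5)).validate()


class TestCoupledSeries:
    def test_structure_and_reproducibility(self):
        x, y = synth.generate_coupled_series(300, beta=0.8, lag=2, seed=5)
        x2, y2 = synth.generate_coupled_series(300, beta=0.8, lag=2, seed=5)
        assert np.array_equal(x, x2) and np.array_equal(y, y2)
        # y is exactly beta*lagged x plus the noise realization at beta=0
        _, eps = synth.generate_coupled_series(300, beta=0.0, lag=2, seed=5)
        assert np.allclose(y[2:], eps[2:] + 0.8 * x[:-2])

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            synth.generate_coupled_series(5, beta=0.5, lag=1)

    def test_nonfinite_parameters_are_errors(self):
        with pytest.raises(ValueError):
            synth.generate_coupled_series(100, beta=float("nan"), lag=1)
        with pytest.raises(ValueError):
            synth.generate_coupled_series(100, beta=0.5, lag=1, noise_sd=0.0)


class TestRatingPairs:
    def test_expert_table_round_trip(self):
        cells = [[62, 17, 5], [22, 40, 16], [11, 13, 75]]
        pairs = synth.generate_rating_pairs(cells, seed=11)
        assert len(pairs) == 261
        assert build_confusion_matrix(pairs).cells == tuple(map(tuple, cells))

    def test_zero_matrix_gives_empty_list(self):
        assert synth.generate_rating_pairs(np.zeros((3, 3), dtype=int)) == []

    def test_identity_matrix_fully_concordant(self):
        pairs = synth.generate_rating_pairs(np.eye(3, dtype=int))
        assert sorted(pairs) == [(-1, -1), (0, 0), (1, 1)]

    def test_non_integer_cells_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            synth.generate_rating_pairs([[1.5, 0, 0], [0, 0, 0], [0, 0, 0]])

    @given(st.lists(st.lists(st.integers(0, 6), min_size=3, max_size=3),
                    min_size=3, max_size=3),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_cross_tabulation_round_trip(self, cells, seed):
        pairs = synth.generate_rating_pairs(cells, seed=seed)
        assert len(pairs) == int(np.sum(cells))
        if pairs:
            assert build_confusion_matrix(pairs).cells == tuple(map(tuple, cells))
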