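"""Granger-causality tests linking a term's daily mentions to daily sentiment.

A mention series x Granger-causes a sentiment series y when lagged values
of x improve the prediction of y beyond y's own lags.  The test compares
two nested ordinary-least-squares autoregressions:

    restricted:    y_t ~ 1 + y_{t-1} ... y_{t-L}
    unrestricted:  y_t ~ 1 + y_{t-1} ... y_{t-L} + x_{t-1} ... x_{t-L}

and forms F = ((RSS_r - RSS_u)/L) / (RSS_u/(n_eff - 2L - 1)) with
n_eff = n - L usable observations, referred to the F(L, n_eff - 2L - 1)
distribution.

Candidate terms are ranked by the smaller of two p-values, against the
daily positive-share and the daily negative-share series separately, so a
term coupled to either polarity is surfaced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .corpus_io import Corpus
from .sentiment import daily_series, daily_sentiment_shares


@dataclass(frozen=True)
class GrangerResult:
    """Outcome of one mentions→sentiment Granger test."""

    term: str
    lag: int
    F: float
    p_value: float
    n_effective: int
    degenerate: bool = False  # constant input; test carries no information
    direction: str = "mentions->sentiment"


def _lag_matrix(v: np.ndarray, lag: int) -> np.ndarray:
    """Columns v_{t-1} .. v_{t-lag} for t = lag .. n-1."""
    return np.column_stack([v[lag - j: len(v) - j] for j in range(1, lag + 1)])


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def granger_test(x: np.ndarray, y: np.ndarray, lag: int = 1,
                 term: str = "") -> GrangerResult:
    """Test whether lagged x improves OLS prediction of y.

    Raises on constant y or series shorter than ``10 * lag``; a constant
    x yields a degenerate (uninformative) result with p = 1 rather than
    an error, so batch ranking over candidate terms never aborts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    n = len(y)
    if n <= 10 * lag:
        raise ValueError(f"series length {n} too short for lag {lag} (need > {10 * lag})")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series contain non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; Granger test undefined")

    n_eff = n - lag
    df_denom = n_eff - 2 * lag - 1
    y_t = y[lag:]
    ones = np.ones((n_eff, 1))
    X_r = np.hstack([ones, _lag_matrix(y, lag)])
    if np.ptp(x) == 0:
        return GrangerResult(term=term, lag=lag, F=0.0, p_value=1.0,
                             n_effective=n_eff, degenerate=True)
    X_u = np.hstack([X_r, _lag_matrix(x, lag)])
    rss_r = _rss(X_r, y_t)
    rss_u = _rss(X_u, y_t)
    # guard against tiny negative differences from floating-point noise
    num = max(rss_r - rss_u, 0.0) / lag
    if rss_u <= 0:
        return GrangerResult(term=term, lag=lag, F=np.inf, p_value=0.0,
                             n_effective=n_eff)
    F = num / (rss_u / df_denom)
    p = float(stats.f.sf(F, lag, df_denom))
    return GrangerResult(term=term, lag=lag, F=float(F), p_value=p,
                         n_effective=n_eff)


@dataclass(frozen=True)
class TermAssociation:
    """Granger results for one candidate term against both polarity series."""

    term: str
    positive: GrangerResult
    negative: GrangerResult
    p_min: float
    significant: bool

    @property
    def degenerate(self) -> bool:
        return self.positive.degenerate and self.negative.degenerate


def rank_terms(corpus: Corpus, scores: list, terms: list[str],
               lag: int = 1, alpha: float = 0.05,
               lags: list[int] | None = None,
               bh_correct: bool = False) -> list[TermAssociation]:
    """Rank candidate terms by how strongly their mention series predicts
    daily sentiment.

    Each term is tested against the daily positive-share and
    negative-share series separately; terms are ordered by the minimum of
    the two p-values and flagged when it falls below ``alpha``.

    ``lags`` scans several lag orders with a Bonferroni correction across
    them; ``bh_correct`` applies Benjamini–Hochberg across terms (off by
    default — raw per-term p-values are reported otherwise).
    """
    if not terms:
        raise ValueError("need at least one candidate term")
    shares = daily_sentiment_shares(corpus, scores)
    results: list[TermAssociation] = []
    scan = lags if lags else [lag]
    for term in terms:
        series = daily_series(corpus, scores, term)
        x = series.mentions.astype(float)
        best_pos, best_neg = None, None
        for L in scan:
            rp = granger_test(x, shares["pos_share"].to_numpy(), lag=L, term=term)
            rn = granger_test(x, shares["neg_share"].to_numpy(), lag=L, term=term)
            if len(scan) > 1:  # Bonferroni across scanned lags
                rp = GrangerResult(term=term, lag=rp.lag, F=rp.F,
                                   p_value=min(1.0, rp.p_value * len(scan)),
                                   n_effective=rp.n_effective,
                                   degenerate=rp.degenerate)
                rn = GrangerResult(term=term, lag=rn.lag, F=rn.F,
                                   p_value=min(1.0, rn.p_value * len(scan)),
                                   n_effective=rn.n_effective,
                                   degenerate=rn.degenerate)
            if best_pos is None or rp.p_value < best_pos.p_value:
                best_pos = rp
            if best_neg is None or rn.p_value < best_neg.p_value:
                best_neg = rn
        p_min = min(best_pos.p_value, best_neg.p_value)
        results.append(TermAssociation(term=term, positive=best_pos,
                                       negative=best_neg, p_min=p_min,
                                       significant=False))
    results.sort(key=lambda r: (r.p_min, r.term))

    pvals = np.array([r.p_min for r in results])
    if bh_correct:
        m = len(pvals)
        q = pvals * m / np.arange(1, m + 1)  # pvals already sorted ascending
        adj = np.minimum(np.minimum.accumulate(q[::-1])[::-1], 1.0)
        sig = adj < alpha
    else:
        sig = pvals < alpha
    return [
        TermAssociation(term=r.term, positive=r.positive, negative=r.negative,
                        p_min=r.p_min,
                        significant=bool(s) and not r.degenerate)
        for r, s in zip(results, sig)
    ]
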