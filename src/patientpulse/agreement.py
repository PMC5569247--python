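"""Rater-agreement analysis on ordinal Likert ratings.

Two raters score each item on an ordered scale (here the 3-point attitude
scale -1/0/+1).  Their agreement is summarized by a k×k confusion matrix
and by weighted Cohen's kappa,

    kappa = (P_o(w) - P_e(w)) / (1 - P_e(w)),

where P_o(w) = sum_ij w_ij n_ij / N is the weighted observed agreement,
P_e(w) = sum_ij w_ij r_i c_j / N^2 the chance-expected agreement from the
marginals, and w_ij = 1 - ((i - j)/(k - 1))^2 the quadratic ("square")
agreement weights that discount disagreements by the squared category
distance.  With integer cell counts every quantity is an exact rational
number; computation uses exact fractions and rounds only for display.

Verbal interpretation follows the conventional Landis–Koch bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

#: Landis–Koch interpretation bands: (upper bound, label); kappa <= bound.
#: Values below 0 are "poor", handled before the band lookup.
_KAPPA_BANDS = [
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """k×k cross-tabulation of two raters' ordinal scores.

    Rows index rater A's score, columns rater B's, both ordered by
    ``scores``.
    """

    scores: tuple[int, ...]
    cells: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        k = len(self.scores)
        if k < 2:
            raise ValueError("need at least two score levels")
        if len(self.cells) != k or any(len(r) != k for r in self.cells):
            raise ValueError(f"cells must be {k}x{k}")
        if any(c < 0 or c != int(c) for row in self.cells for c in row):
            raise ValueError("cells must be nonnegative integers")

    @property
    def k(self) -> int:
        return len(self.scores)

    @property
    def N(self) -> int:
        return sum(sum(r) for r in self.cells)

    @property
    def row_marginals(self) -> tuple[int, ...]:
        return tuple(sum(r) for r in self.cells)

    @property
    def col_marginals(self) -> tuple[int, ...]:
        return tuple(sum(r[j] for r in self.cells) for j in range(self.k))

    def to_array(self) -> np.ndarray:
        return np.array(self.cells, dtype=int)


@dataclass(frozen=True)
class KappaResult:
    """Weighted-kappa summary for one confusion matrix."""

    weight_scheme: str
    weights: tuple[tuple[float, ...], ...]
    weighted_agreement_numerator: float  # sum_ij w_ij n_ij
    P_o_w: float
    P_e_w: float
    kappa: float
    kappa_fraction: Fraction
    label: str

    @property
    def kappa_display(self) -> float:
        """Kappa rounded to 4 decimals for reporting."""
        return float(round(self.kappa, 4))


def build_confusion_matrix(pairs: Sequence[tuple[int, int]],
                           scores: Sequence[int] = (-1, 0, 1)) -> ConfusionMatrix:
    """Cross-tabulate paired ratings; cell[i][j] counts pairs
    (scores[i], scores[j])."""
    if not pairs:
        raise ValueError("no rating pairs given")
    index = {s: i for i, s in enumerate(scores)}
    k = len(scores)
    cells = [[0] * k for _ in range(k)]
    for idx, (a, b) in enumerate(pairs):
        if a not in index or b not in index:
            raise ValueError(
                f"pair {idx}: rating ({a}, {b}) outside scale {tuple(scores)}"
            )
        cells[index[a]][index[b]] += 1
    return ConfusionMatrix(scores=tuple(scores),
                           cells=tuple(tuple(r) for r in cells))


def _weight_fractions(k: int, scheme: str) -> list[list[Fraction]]:
    if k < 2:
        raise ValueError("need k >= 2 score levels")
    if scheme == "quadratic":
        return [[1 - Fraction((i - j) ** 2, (k - 1) ** 2) for j in range(k)]
                for i in range(k)]
    if scheme == "linear":
        return [[1 - Fraction(abs(i - j), k - 1) for j in range(k)]
                for i in range(k)]
    if scheme == "unweighted":
        return [[Fraction(int(i == j)) for j in range(k)] for i in range(k)]
    raise ValueError(f"unknown weight scheme {scheme!r}")


def quadratic_weights(k: int) -> np.ndarray:
    """Quadratic agreement weights w_ij = 1 - ((i-j)/(k-1))^2.

    For k=3: unit diagonal, 0.75 for adjacent categories, 0 for the two
    extremes.  k=2 reduces to the identity (unweighted kappa).
    """
    return np.array(_weight_fractions(k, "quadratic"), dtype=float)


def weighted_agreement(m: ConfusionMatrix,
                       w: np.ndarray) -> tuple[float, float]:
    """Weighted observed agreement: (numerator sum_ij w_ij n_ij, P_o_w).

    With identity weights this is plain percent agreement.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (m.k, m.k):
        raise ValueError(f"weight matrix must be {m.k}x{m.k}")
    if m.N == 0:
        raise ValueError("empty confusion matrix")
    numerator = float(np.sum(w * m.to_array()))
    return numerator, numerator / m.N


def expected_weighted_agreement(m: ConfusionMatrix, w: np.ndarray) -> float:
    """Chance-expected weighted agreement sum_ij w_ij r_i c_j / N^2."""
    w = np.asarray(w, dtype=float)
    if m.N == 0:
        raise ValueError("empty confusion matrix")
    r = np.array(m.row_marginals, dtype=float)
    c = np.array(m.col_marginals, dtype=float)
    return float(np.sum(w * np.outer(r, c)) / m.N ** 2)


def weighted_kappa(m: ConfusionMatrix, scheme: str = "quadratic") -> KappaResult:
    """Weighted Cohen's kappa with exact-fraction arithmetic.

    kappa = (P_o_w - P_e_w)/(1 - P_e_w); undefined when the marginals make
    P_e_w = 1 (no room for chance-corrected agreement).
    """
    if m.N == 0:
        raise ValueError("empty confusion matrix")
    wf = _weight_fractions(m.k, scheme)
    n = m.cells
    r, c = m.row_marginals, m.col_marginals
    N = m.N
    num_o = sum(wf[i][j] * n[i][j] for i in range(m.k) for j in range(m.k))
    p_o = Fraction(num_o, N)
    p_e = sum(wf[i][j] * r[i] * c[j] for i in range(m.k) for j in range(m.k)) \
        / Fraction(N * N)
    if p_e == 1:
        raise ValueError("degenerate marginals: expected agreement is 1, kappa undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    return KappaResult(
        weight_scheme=scheme,
        weights=tuple(tuple(float(x) for x in row) for row in wf),
        weighted_agreement_numerator=float(num_o),
        P_o_w=float(p_o),
        P_e_w=float(p_e),
        kappa=float(kappa),
        kappa_fraction=kappa,
        label=interpret_kappa(float(kappa)),
    )


def rating_proportions(m: ConfusionMatrix) -> dict[str, dict[int, int]]:
    """Marginal rating shares per rater, as integer percentages.

    Returns ``{"rater_a": {score: pct}, "rater_b": {...}}`` with
    round-half-up percentages of each score level's marginal count.
    """
    if m.N == 0:
        raise ValueError("empty confusion matrix")

    def pct(count: int) -> int:
        return int(Fraction(100 * count, m.N) + Fraction(1, 2))

    return {
        "rater_a": {s: pct(n) for s, n in zip(m.scores, m.row_marginals)},
        "rater_b": {s: pct(n) for s, n in zip(m.scores, m.col_marginals)},
    }


def interpret_kappa(kappa: float) -> str:
    """Landis–Koch verbal band for a kappa value (kappa <= 1)."""
    if kappa > 1:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0:
        return "poor"
    for bound, label in _KAPPA_BANDS:
        if kappa <= bound:
            return label
    return "almost perfect"
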