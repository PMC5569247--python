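from fractions import Fraction

import numpy as np
import pytest

from patientpulse.agreement import (
    ConfusionMatrix, build_confusion_matrix, expected_weighted_agreement,
    interpret_kappa, quadratic_weights, rating_proportions, weighted_agreement,
    weighted_kappa)
from patientpulse.corpus_io import packaged_ratings

from conftest import EXPERT_CELLS


class TestBuildConfusionMatrix:
    def test_packaged_expert_ratings_reproduce_printed_table(self):
        m = build_confusion_matrix(packaged_ratings())
        assert m.cells == EXPERT_CELLS
        assert m.N == 261
        assert m.row_marginals == (84, 78, 99)
        assert m.col_marginals == (95, 70, 96)

    def test_single_pair(self):
        m = build_confusion_matrix([(1, 1)])
        assert m.cells[2][2] == 1 and m.N == 1

    def test_rating_outside_scale_names_pair(self):
        with pytest.raises(ValueError, match="pair 0"):
            build_confusion_matrix([(2, 0)])

    def test_empty_pairs_is_error(self):
        with pytest.raises(ValueError):
            build_confusion_matrix([])


class TestQuadraticWeights:
    def test_three_levels(self):
        assert np.allclose(quadratic_weights(3),
                           [[1, .75, 0], [.75, 1, .75], [0, .75, 1]])

    def test_two_levels_reduce_to_identity(self):
        assert np.allclose(quadratic_weights(2), np.eye(2))

    @pytest.mark.parametrize("k", [2, 3, 5, 7])
    def test_symmetric_with_unit_diagonal(self, k):
        w = quadratic_weights(k)
        assert np.allclose(w, w.T)
        assert np.allclose(np.diag(w), 1.0)
        assert (w >= 0).all() and (w <= 1).all()

    def test_below_two_levels_is_error(self):
        with pytest.raises(ValueError):
            quadratic_weights(1)


class TestWeightedAgreement:
    def test_printed_numerator_and_percentage(self, expert_matrix):
        num, po = weighted_agreement(expert_matrix, quadratic_weights(3))
        assert num == pytest.approx(228.0)
        assert round(100 * po, 2) == 87.36

    def test_identity_weights_give_raw_percent_agreement(self, expert_matrix):
        num, po = weighted_agreement(expert_matrix, np.eye(3))
        brute = sum(expert_matrix.cells[i][i] for i in range(3))
        assert num == brute == 177
        assert po == pytest.approx(177 / 261)

    def test_perfectly_concordant_matrix(self):
        m = ConfusionMatrix(scores=(-1, 0, 1),
                            cells=((5, 0, 0), (0, 7, 0), (0, 0, 9)))
        assert weighted_agreement(m, quadratic_weights(3))[1] == 1.0

    def test_all_mass_in_zero_weight_corners(self):
        m = ConfusionMatrix(scores=(-1, 0, 1),
                            cells=((0, 0, 4), (0, 0, 0), (6, 0, 0)))
        assert weighted_agreement(m, quadratic_weights(3))[1] == 0.0


class TestExpectedAgreement:
    def test_printed_marginals_brute_force_value(self, expert_matrix):
        pe = expected_weighted_agreement(expert_matrix, quadratic_weights(3))
        assert pe == pytest.approx(43725 / 68121)

    def test_uniform_marginals(self):
        m = ConfusionMatrix(scores=(-1, 0, 1),
                            cells=((1, 1, 1), (1, 1, 1), (1, 1, 1)))
        assert expected_weighted_agreement(m, quadratic_weights(3)) == \
            pytest.approx(6 / 9)

    def test_single_row_and_column(self):
        m = ConfusionMatrix(scores=(-1, 0, 1),
                            cells=((0, 0, 0), (0, 0, 8), (0, 0, 0)))
        assert expected_weighted_agreement(m, quadratic_weights(3)) == \
            pytest.approx(0.75)


class TestWeightedKappa:
    def test_expert_table_kappa_exact_fraction(self, expert_matrix):
        res = weighted_kappa(expert_matrix)
        assert res.kappa_fraction == Fraction(5261, 8132)
        assert res.kappa_display == 0.6470
        assert res.label == "substantial"

    def test_matches_sklearn_quadratic(self, expert_matrix):
        from sklearn.metrics import cohen_kappa_score
        pairs = packaged_ratings()
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        ref = cohen_kappa_score(a, b, weights="quadratic")
        assert weighted_kappa(expert_matrix).kappa == pytest.approx(ref, rel=1e-12)

    def test_perfect_concordance_is_one(self):
        m = ConfusionMatrix(scores=(-1, 0, 1),
                            cells=((3, 0, 0), (0, 4, 0), (0, 0, 5)))
        assert weighted_kappa(m).kappa == 1.0

    def test_kappa_one_only_without_off_diagonal_mass(self):
        m = ConfusionMatrix(scores=(-1, 0, 1),
                            cells=((3, 1, 0), (0, 4, 0), (0, 0, 5)))
        assert weighted_kappa(m).kappa < 1.0

    def test_uniform_cells_give_zero(self):
        m = ConfusionMatrix(scores=(-1, 0, 1),
                            cells=((2, 2, 2), (2, 2, 2), (2, 2, 2)))
        assert weighted_kappa(m).kappa == 0.0

    @pytest.mark.parametrize("scheme", ["quadratic", "linear", "unweighted"])
    def test_independent_raters_give_zero_for_any_scheme(self, scheme):
        r = (1, 2, 3)
        c = (2, 1, 3)
        cells = tuple(tuple(ri * cj for cj in c) for ri in r)
        m = ConfusionMatrix(scores=(-1, 0, 1), cells=cells)
        assert weighted_kappa(m, scheme=scheme).kappa == 0.0

    def test_two_level_quadratic_equals_unweighted(self):
        m = ConfusionMatrix(scores=(0, 1), cells=((12, 3), (5, 20)))
        quad = weighted_kappa(m, scheme="quadratic").kappa
        unw = weighted_kappa(m, scheme="unweighted").kappa
        assert quad == pytest.approx(unw, abs=1e-15)

    def test_degenerate_marginals_undefined(self):
        m = ConfusionMatrix(scores=(0, 1), cells=((7, 0), (0, 0)))
        with pytest.raises(ValueError, match="degenerate"):
            weighted_kappa(m)


class TestProportionsAndInterpretation:
    def test_expert_marginal_percentages(self, expert_matrix):
        props = rating_proportions(expert_matrix)
        # row rater: senior gastroenterologist
        assert props["rater_a"] == {-1: 32, 0: 30, 1: 38}
        # column rater (computer scientist): neutral share 70/261 -> 27%
        assert props["rater_b"][0] == 27

    def test_uniform_marginals_round_to_third(self):
        m = ConfusionMatrix(scores=(-1, 0, 1),
                            cells=((87, 0, 0), (0, 87, 0), (0, 0, 87)))
        assert rating_proportions(m)["rater_a"] == {-1: 33, 0: 33, 1: 33}

    @pytest.mark.parametrize("kappa,label", [
        (-0.2, "poor"),
        (0.15, "slight"),
        (0.30, "fair"),
        (0.50, "moderate"),
        (0.6470, "substantial"),
        (0.90, "almost perfect"),
        (1.0, "almost perfect"),
    ])
    def test_landis_koch_bands(self, kappa, label):
        assert interpret_kappa(kappa) == label

    def test_kappa_above_one_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.2)
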