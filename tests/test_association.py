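"""Correlation, discretization, entropy estimators, and MI."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffconn import (
    AssociationError,
    association_matrix,
    discretize,
    entropy,
    mi_from_joint_counts,
    mutual_information,
    pearson,
    sample_gaussian,
    spearman,
    toeplitz_matrix,
)
from diffconn.association import default_n_bins

count_tables = st.lists(st.integers(min_value=0, max_value=50),
                        min_size=2, max_size=12).filter(lambda c: sum(c) > 0)


class TestCorrelation:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 4), (1, 3, 3), 0.7559),
        ],
    )
    def test_pearson_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected, abs=1e-4)

    def test_pearson_symmetric_and_affine_invariant(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        r = pearson(x, y)
        assert pearson(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson(3.0 * x + 5.0, y) == pytest.approx(r, abs=1e-12)

    def test_pearson_errors(self):
        with pytest.raises(AssociationError):
            pearson((1, 1, 1), (1, 2, 3))
        with pytest.raises(AssociationError):
            pearson((1, 2, 3), (1, 2))

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (math.e, math.e ** 2, math.e ** 3), 1.0),
            ((1, 2, 3), (3, 1, 2), -0.5),
            ((1, 1, 2), (1, 1, 2), 1.0),
        ],
    )
    def test_spearman_values(self, x, y, expected):
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_spearman_equals_pearson_on_ranks(self, rng):
        from scipy.stats import rankdata

        x = rng.integers(0, 5, size=40).astype(float)  # heavy ties
        y = rng.standard_normal(40)
        assert spearman(x, y) == pytest.approx(
            pearson(rankdata(x), rankdata(y)), abs=1e-12)

    def test_spearman_monotone_invariance(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y), abs=1e-12)


class TestDiscretize:
    def test_tertiles_of_nine(self):
        d = discretize(np.arange(1, 10), n_bins=3)
        assert d.labels.tolist() == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_constant_input_single_bin(self):
        d = discretize(np.full(10, 3.5), n_bins=4)
        assert set(d.labels) == {1}
        assert d.n_occupied == 1

    def test_default_bins_cube_root(self):
        assert default_n_bins(27) == 3
        assert default_n_bins(28) == 4
        assert discretize(np.arange(27)).n_bins == 3

    def test_equal_frequency_balance(self, rng):
        x = rng.standard_normal(100)
        counts = discretize(x, n_bins=4).counts
        assert counts.max() - counts.min() <= 1

    def test_equal_width_scheme(self):
        d = discretize(np.array([0.0, 0.1, 0.2, 5.0, 9.9, 10.0]), n_bins=2,
                       scheme="equal_width")
        assert d.labels.tolist() == [1, 1, 1, 2, 2, 2]

    def test_too_many_bins_rejected(self):
        with pytest.raises(AssociationError):
            discretize(np.arange(3), n_bins=5)


class TestEntropy:
    def test_worked_example_empirical(self):
        # probabilities 0.2 / 0.7 / 0.1
        assert entropy((2, 7, 1)).value == pytest.approx(0.8018, abs=5e-5)

    def test_single_bin_is_zero_for_all_estimators(self):
        for est in ("empirical", "miller_madow", "shrinkage",
                    "schurmann_grassberger"):
            assert entropy((10,), est).value == pytest.approx(0.0, abs=1e-12)

    def test_miller_madow_offset(self):
        assert entropy((2, 7, 1), "miller_madow").value == pytest.approx(
            0.8018 + 2 / 20, abs=5e-5)

    def test_uniform_four_bins(self):
        assert entropy((5, 5, 5, 5)).value == pytest.approx(np.log(4), abs=1e-12)

    def test_shrinkage_worked_example(self):
        # lambda* = (1 - 0.54) / (9 * 0.20667) = 0.24731, then plug-in of the
        # shrunken frequencies (independently evaluated by hand)
        est = entropy((2, 7, 1), "shrinkage")
        assert est.lambda_star == pytest.approx(0.24731, abs=1e-4)
        lam = est.lambda_star
        p = lam / 3 + (1 - lam) * np.array([0.2, 0.7, 0.1])
        assert est.value == pytest.approx(float(-(p * np.log(p)).sum()), abs=1e-12)
        assert est.value == pytest.approx(0.933, abs=1e-3)

    def test_schurmann_grassberger_default_prior(self):
        est = entropy((2, 7, 1), "schurmann_grassberger")
        assert est.prior_N == pytest.approx(1 / 3)
        # independent evaluation of the digamma formula with N = 1/3
        from scipy.special import digamma

        c = np.array([2.0, 7.0, 1.0])
        n, big_n = 10.0, 1 / 3
        tot = n + 3 * big_n
        expected = float(np.sum((c + big_n) * (digamma(tot + 1) -
                                               digamma(c + big_n + 1))) / tot)
        assert est.value == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(counts=count_tables)
    def test_miller_madow_minus_empirical_identity(self, counts):
        c = np.asarray(counts)
        h_emp = entropy(c).value
        h_mm = entropy(c, "miller_madow").value
        k, n = np.count_nonzero(c), c.sum()
        assert h_mm - h_emp == pytest.approx((k - 1) / (2 * n), abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(counts=count_tables)
    def test_empirical_matches_direct_plugin(self, counts):
        c = np.asarray(counts, dtype=float)
        p = c[c > 0] / c.sum()
        assert entropy(c).value == pytest.approx(
            float(-(p * np.log(p)).sum()), abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(counts=count_tables)
    def test_empirical_bounds_and_shrinkage_intensity(self, counts):
        c = np.asarray(counts)
        h = entropy(c).value
        assert -1e-12 <= h <= np.log(np.count_nonzero(c)) + 1e-12
        lam = entropy(c, "shrinkage").lambda_star
        assert 0.0 <= lam <= 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(AssociationError):
            entropy((0, 0, 0))


class TestMutualInformation:
    def test_diagonal_joint_table(self):
        assert mi_from_joint_counts([[5, 0], [0, 5]]) == pytest.approx(
            np.log(2), abs=1e-12)

    def test_independent_uniform_joint(self):
        assert mi_from_joint_counts([[2, 2], [2, 2]]) == pytest.approx(0.0, abs=1e-12)

    def test_self_mi_equals_entropy(self, rng):
        x = rng.standard_normal(200)
        d = discretize(x)
        assert mutual_information(x, x) == pytest.approx(
            entropy(d.counts).value, abs=1e-12)

    def test_gaussian_mi_near_closed_form(self, rng):
        X = sample_gaussian(toeplitz_matrix(2, 0.9), 10000, rng)
        mi = mutual_information(X[:, 0], X[:, 1])
        assert mi == pytest.approx(-0.5 * np.log(1 - 0.81), abs=0.15)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(joint=st.lists(st.lists(st.integers(0, 20), min_size=2, max_size=4),
                          min_size=2, max_size=4)
           .filter(lambda j: len({len(r) for r in j}) == 1 and sum(map(sum, j)) > 0))
    def test_empirical_mi_nonnegative(self, joint):
        assert mi_from_joint_counts(joint) >= -1e-10

    def test_mi_monotone_in_correlation(self, rng):
        med = {}
        for rho in (0.0, 0.3, 0.6, 0.9):
            vals = []
            for _ in range(20):
                X = sample_gaussian(toeplitz_matrix(2, rho) if rho else
                                    toeplitz_matrix(2, 0.0), 5000, rng)
                vals.append(mutual_information(X[:, 0], X[:, 1]))
            med[rho] = np.median(vals)
        assert med[0.0] < med[0.3] < med[0.6] < med[0.9]


class TestAssociationMatrix:
    def test_identical_columns_pearson(self, rng):
        x = rng.standard_normal(20)
        A = association_matrix(np.column_stack([x, x, rng.standard_normal(20)]))
        assert A.weights[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_all_measures(self, rng):
        X = rng.standard_normal((30, 6))
        for measure, est in [("pearson", None), ("spearman", None),
                             ("mi", "miller_madow")]:
            W = association_matrix(X, measure, estimator=est).weights
            assert np.allclose(W, W.T)

    def test_delegates_to_pairwise_pearson(self):
        A = association_matrix(np.array([[1.0, 1.0], [2.0, 3.0], [4.0, 3.0]]))
        assert A.weights[0, 1] == pytest.approx(0.7559, abs=1e-4)

    def test_constant_feature_warns_and_zeroes(self, rng):
        X = np.column_stack([rng.standard_normal(20), np.full(20, 2.0),
                             rng.standard_normal(20)])
        with pytest.warns(UserWarning, match="constant"):
            A = association_matrix(X)
        assert A.weights[1, 0] == 0.0 and A.weights[1, 2] == 0.0
        with pytest.warns(UserWarning, match="constant"):
            M = association_matrix(X, "mi")
        assert M.weights[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_dataframe_feature_names(self, rng):
        import pandas as pd

        df = pd.DataFrame(rng.standard_normal((10, 3)), columns=list("abc"))
        assert association_matrix(df).feature_names == ("a", "b", "c")

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(AssociationError):
            association_matrix(rng.standard_normal((2, 4)))
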