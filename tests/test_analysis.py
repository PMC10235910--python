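"""Analysis suite: clustering, PCA, separation metrics, information
measures, the competition energy and paired statistics.

Each numerically nontrivial operation is checked against an independent
oracle: explicit matrix inversion, exhaustive permutation enumeration,
hand-evaluated sums, or exact sign-assignment distributions.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ltd_templates
from syncomp import analysis


class TestClusterWeights:
    def test_depressed_profile_top2(self, overlapping):
        theta = 0.2
        row = np.array([-theta, 1 - theta, 1 - theta, -theta] + [-theta] * 5)
        assign = analysis.cluster_weights(row[None, :], "top2_units")
        assert assign.labels == [(1, 2)]

    def test_three_way_tie_breaks_to_lowest_indices(self):
        row = np.zeros(9)
        row[[3, 5, 7]] = 1.0
        assign = analysis.cluster_weights(row[None, :], "top2_units")
        assert assign.labels == [(3, 5)]

    def test_weak_rows_unresolved_and_excluded(self):
        W = np.vstack([np.zeros(9), np.full(9, 0.05), np.eye(9)[2] + np.eye(9)[3]])
        W[2] *= 0.9
        assign = analysis.cluster_weights(W, "top2_units")
        assert assign.labels[0] is None and assign.labels[1] is None
        assert assign.labels[2] == (2, 3)
        assert assign.n_resolved == 1

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            analysis.cluster_weights(np.zeros((3, 9)))

    def test_nearest_fundamental_scheme(self, overlapping):
        W = overlapping.patterns[[2, 0]] + 0.01
        assign = analysis.cluster_weights(W, "nearest_fundamental", ps=overlapping)
        assert assign.labels == [2, 0]

    def test_major_categories_filters_stragglers(self):
        rows = [np.eye(9)[1] + np.eye(9)[2]] * 40 + [np.eye(9)[5] + np.eye(9)[6]]
        assign = analysis.cluster_weights(np.array(rows), "top2_units")
        assert analysis.major_categories(assign) == {(1, 2)}


class TestCosineToFundamentals:
    def test_prototype_rows_score_one(self, overlapping):
        sims = analysis.cosine_to_fundamentals(overlapping.patterns[[2]], overlapping)
        assert sims[0, 2] == pytest.approx(1.0)

    def test_orthogonal_and_zero_rows_score_zero(self, overlapping):
        W = np.vstack([np.eye(9)[4], np.zeros(9)])  # unit 4 is in no prototype
        sims = analysis.cosine_to_fundamentals(W, overlapping)
        np.testing.assert_allclose(sims, 0.0, atol=1e-12)

    def test_ltp_profile_has_no_pattern_preference(self, overlapping):
        from conftest import EQ_LTP_PROFILE

        sims = analysis.cosine_to_fundamentals(EQ_LTP_PROFILE[None, :], overlapping)
        assert sims[0, 0] == pytest.approx(sims[0, 2])
        assert np.ptp(sims[0]) < 1e-12  # identical similarity to all four


class TestPca:
    def test_collinear_data_explained_by_first_component(self):
        t = np.linspace(-1, 1, 20)
        X = np.column_stack([2 * t, -t])
        proj, evr, _ = analysis.pca_project(X, 1)
        assert evr[0] == pytest.approx(1.0)
        assert proj.shape == (20, 1)

    def test_mean_point_projects_to_origin(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        _, _, comps = analysis.pca_project(X, 2)
        np.testing.assert_allclose(comps @ (X.mean(0) - X.mean(0)), 0.0)

    def test_eigenvalues_match_characteristic_polynomial_roots(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 3)) @ np.diag([3.0, 1.0, 0.2])
        _, evr, _ = analysis.pca_project(X, 3)
        Xc = X - X.mean(0)
        cov = Xc.T @ Xc / 4
        roots = np.sort(np.roots(np.poly(cov)).real)[::-1]  # independent solve
        np.testing.assert_allclose(evr, roots / roots.sum(), atol=1e-8)

    def test_rank_exceeded_rejected(self):
        X = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="rank"):
            analysis.pca_project(X, 2)

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        _, _, c1 = analysis.pca_project(X, 3)
        _, _, c2 = analysis.pca_project(X[::-1], 3)
        np.testing.assert_allclose(c1, c2, atol=1e-8)


class TestMahalanobis:
    def test_identical_clusters_distance_zero(self):
        A = np.random.default_rng(0).normal(size=(20, 3))
        assert analysis.mahalanobis_between(A, A.copy()) == pytest.approx(0.0, abs=1e-9)

    def test_identity_covariance_reduces_to_euclidean(self):
        # clusters whose pooled within-cluster covariance is exactly I
        V = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        V = V * np.sqrt(6 / 4)  # sample covariance of V (ddof over 2n-2) = I
        A = V + [5.0, 0.0]
        B = V + [0.0, 2.0]
        d = analysis.mahalanobis_between(A, B, reg=0.0)
        assert d == pytest.approx(np.sqrt(5**2 + 2**2), rel=1e-9)

    def test_hand_inverted_two_dimensional_oracle(self):
        A = np.array([[0.0, 0.0], [2.0, 1.0], [1.0, 2.0], [-1.0, 1.0]])
        B = np.array([[4.0, 3.0], [6.0, 5.0], [5.0, 3.0], [5.0, 5.0]])
        Xc = np.vstack([A - A.mean(0), B - B.mean(0)])
        S = Xc.T @ Xc / (len(Xc) - 2)
        d = A.mean(0) - B.mean(0)
        expected = np.sqrt(d @ np.linalg.inv(S) @ d)  # explicit inversion
        assert analysis.mahalanobis_between(A, B, reg=0.0) == pytest.approx(expected)

    def test_symmetry_and_singular_rejection(self):
        A = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])  # degenerate spread
        B = A + [0.0, 1.0]
        assert analysis.mahalanobis_between(A, B) == pytest.approx(
            analysis.mahalanobis_between(B, A)
        )
        with pytest.raises(ValueError, match="reg"):
            analysis.mahalanobis_between(A, B, reg=0.0)

    def test_separation_table_covers_six_pairs(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 4, 200)
        acts = np.eye(4)[labels] + rng.normal(0, 0.3, (200, 4))
        table = analysis.separation_table(acts, labels, rule_tag="test")
        assert set(table.distances) == set(analysis.ALL_PAIRS)
        assert np.all(table.values() >= 0)
        frame = table.to_frame()
        assert list(frame.columns) == ["pair", "mahalanobis", "rule"]


class TestMutualInformation:
    def test_perfect_balanced_prediction_saturates_at_log_c(self):
        labels = np.repeat(np.arange(10), 50)
        assert analysis.mutual_information_labels(labels, labels) == pytest.approx(
            np.log(10)
        )

    def test_two_by_two_table_matches_hand_sum(self):
        # joint table [[40, 10], [10, 40]] over 100 samples
        a = np.repeat([0, 0, 1, 1], [40, 10, 10, 40])
        b = np.repeat([0, 1, 0, 1], [40, 10, 10, 40])
        expected = 2 * 0.4 * np.log(0.4 / 0.25) + 2 * 0.1 * np.log(0.1 / 0.25)
        assert analysis.mutual_information_labels(a, b) == pytest.approx(expected)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 20_000)
        b = rng.integers(0, 4, 20_000)
        assert analysis.mutual_information_labels(a, b) < 0.01

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_by_log_c(self, seed):
        rng = np.random.default_rng(seed)
        C = int(rng.integers(2, 6))
        a = rng.integers(0, C, 500)
        b = rng.integers(0, C, 500)
        assert analysis.mutual_information_labels(a, b) <= np.log(C) + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            analysis.mutual_information_labels([], [])


class TestAdjustedCosine:
    def test_exhaustive_enumeration_oracle(self):
        """For length-3 vectors the shuffled baseline is the mean over all
        6 x 6 paired permutations; the estimator converges to it."""
        a = np.array([3.0, 1.0, 0.2])
        b = np.array([0.5, 2.0, 1.0])
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        perms = list(itertools.permutations(range(3)))
        base = np.mean(
            [a[list(p)] @ b[list(q)] for p in perms for q in perms]
        ) / (na * nb)
        expected = a @ b / (na * nb) - base
        got = analysis.adjusted_cosine(a, b, n_shuffles=40_000, seed=0)
        assert got == pytest.approx(expected, abs=5e-3)

    def test_identical_structured_vector_scores_positive(self):
        a = np.zeros(20)
        a[3] = 5.0
        assert analysis.adjusted_cosine(a, a, seed=1) > 0.5

    def test_exchangeable_noise_scores_near_zero(self):
        rng = np.random.default_rng(2)
        vals = [
            analysis.adjusted_cosine(rng.uniform(0, 1, 50), rng.uniform(0, 1, 50),
                                     n_shuffles=50, seed=k)
            for k in range(30)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            analysis.adjusted_cosine(np.zeros(5), np.ones(5))


class TestEnergy:
    def test_identical_rows_have_zero_energy(self):
        W = np.tile([0.3, 0.7, 0.1], (5, 1))
        mom = analysis.SecondMoments(np.ones(3), np.full((3, 3), 0.5))
        for i in range(5):
            assert analysis.energy(W, i, mom) == pytest.approx(0.0)

    def test_diagonal_moments_reduce_to_first_sum(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        xsq = np.array([2.0, 3.0])
        mom = analysis.SecondMoments(xsq, np.diag(xsq))
        d = W[0] - W[1:].mean(axis=0)
        assert analysis.energy(W, 0, mom) == pytest.approx(-0.5 * d**2 @ xsq)

    def test_two_neuron_hand_arithmetic(self):
        """N=2, D=2 evaluated term by term by hand."""
        W = np.array([[1.0, 0.5], [0.2, 0.8]])
        mom = analysis.SecondMoments(
            xsq=np.array([1.5, 2.0]),
            cross=np.array([[1.5, 0.4], [0.4, 2.0]]),
        )
        # leave-one-out mean for neuron 0 is just row 1
        d0, d1 = 1.0 - 0.2, 0.5 - 0.8
        expected = -0.5 * (d0**2 * 1.5 + d1**2 * 2.0) - d0 * d1 * 0.4
        assert analysis.energy(W, 0, mom) == pytest.approx(expected)

    def test_energy_unbounded_below_as_one_neuron_dominates(self):
        """Growing one row away from the population mean lowers the energy
        without bound — the instability the maturation cap prevents."""
        mom = analysis.SecondMoments(np.ones(3), np.eye(3))
        base = np.tile([0.2, 0.2, 0.2], (4, 1))
        energies = []
        for scale in (1.0, 5.0, 25.0):
            W = base.copy()
            W[0] *= scale
            energies.append(analysis.energy(W, 0, mom))
        assert energies[0] > energies[1] > energies[2]

    def test_single_neuron_rejected(self):
        mom = analysis.SecondMoments(np.ones(2), np.eye(2))
        with pytest.raises(ValueError):
            analysis.energy(np.ones((1, 2)), 0, mom)

    def test_moments_from_samples_consistent(self, overlapping):
        from syncomp.patterns import make_sample_stream

        st_ = make_sample_stream(overlapping, 20_000, 0.1, 0)
        mom = analysis.SecondMoments.from_samples(st_.samples)
        # <x_2^2> = mean over patterns of xi_2^2 plus noise variance
        assert mom.xsq[2] == pytest.approx(0.5 + 0.01, abs=0.02)
        np.testing.assert_allclose(mom.cross, mom.cross.T)


class TestPairedComparison:
    @staticmethod
    def _table(vals, tag=""):
        return analysis.SeparationTable(
            dict(zip(analysis.ALL_PAIRS, vals)), rule_tag=tag
        )

    def test_identical_tables_conventions(self):
        t = self._table([1.0, 2, 3, 4, 5, 6])
        rep = analysis.paired_rule_comparison(t, t)
        assert np.isnan(rep["wilcoxon_statistic"]) and rep["wilcoxon_p"] == 1.0
        assert rep["f_statistic"] == pytest.approx(1.0)

    def test_equal_variances_give_unit_f(self):
        a = self._table([1.0, 2, 3, 4, 5, 6])
        b = self._table([11.0, 12, 13, 14, 15, 16])
        rep = analysis.paired_rule_comparison(a, b)
        assert rep["f_statistic"] == pytest.approx(1.0)

    def test_signed_rank_matches_exact_enumeration(self):
        """The exact Wilcoxon p-value equals the tail probability over all
        2^6 sign assignments of the ranked absolute differences."""
        a = self._table([3.1, 4.5, 2.2, 5.0, 3.9, 4.1])
        b = self._table([1.0, 2.0, 2.5, 1.5, 2.0, 3.0])
        rep = analysis.paired_rule_comparison(a, b)
        diffs = a.values() - b.values()
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        w_obs = min(ranks[diffs > 0].sum(), ranks[diffs < 0].sum())
        count = 0
        for signs in itertools.product([0, 1], repeat=6):
            w = min(
                sum(r for r, s in zip(ranks, signs) if s),
                sum(r for r, s in zip(ranks, signs) if not s),
            )
            count += w <= w_obs
        assert rep["wilcoxon_p"] == pytest.approx(count / 64)

    def test_mismatched_pairs_rejected(self):
        a = self._table([1.0, 2, 3, 4, 5, 6])
        b = analysis.SeparationTable({(0, 1): 1.0})
        with pytest.raises(ValueError):
            analysis.paired_rule_comparison(a, b)


class TestCollapseAndEntropy:
    def test_identical_responses_are_fully_collapsed(self):
        acts = np.ones((40, 5))
        labels = np.repeat([0, 1, 2, 3], 10)
        assert analysis.within_group_collapse(acts, labels) == 1.0

    def test_separated_responses_have_low_ratio(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1, 2, 3], 25)
        acts = 10 * np.eye(4)[labels] + rng.normal(0, 0.1, (100, 4))
        assert analysis.within_group_collapse(acts, labels) < 0.1

    def test_partition_entropy_limits(self):
        same = np.tile([0.5, 0.5], (4, 1))
        assert analysis.response_partition_entropy(same) == 0.0
        distinct = np.eye(4)
        assert analysis.response_partition_entropy(distinct) == pytest.approx(np.log(4))

    def test_partition_entropy_tolerance_merges_near_duplicates(self):
        R = np.array([[0.0, 0.0], [0.05, 0.0], [1.0, 1.0], [1.0, 1.04]])
        assert analysis.response_partition_entropy(R, tol=0.1) == pytest.approx(np.log(2))


class TestLtdGroupStructure:
    def test_overlap_profiles_split_into_two_groups_peaking_at_2_and_6(
        self, ltd_overlap_result
    ):
        """Depression on the overlapping task yields two profile groups
        whose peaks sit at the shared units 2 and 6."""
        W = ltd_overlap_result.tail_mean
        peaks = set(W.argmax(axis=1))
        assert peaks == {2, 6}
        counts = np.bincount(W.argmax(axis=1), minlength=9)
        assert counts[2] >= 20 and counts[6] >= 20

    def test_nonoverlap_templates_carry_signed_structure(self, nonoverlapping):
        T = ltd_templates(nonoverlapping)
        assert T.shape == (4, 9)
        assert np.all(T[nonoverlapping.patterns > 0] == 0.8)
        assert np.all(T[nonoverlapping.patterns == 0] == -0.2)
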