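import numpy as np
import pytest

import oracles
from fsda.core_da import (
    ClassStatistics,
    LabelledFeatures,
    compute_class_statistics,
    first_direction,
    fisher_criterion,
    fit_basis,
    fit_basis_from_stats,
    load_basis,
    next_direction,
    project,
    save_basis,
)
from fsda.errors import (
    DegenerateClassError,
    NoDiscriminantDirectionError,
    SubspaceExhausted,
    ValidationError,
)


class TestLabelledFeatures:
    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            LabelledFeatures(np.array([[1.0, np.nan]]), np.array([1]))

    def test_rejects_single_class(self):
        with pytest.raises(ValidationError):
            LabelledFeatures(np.ones((3, 2)), np.array([1, 1, 1]))

    def test_class_order_is_sorted(self):
        data = LabelledFeatures(np.eye(4), np.array([5, 2, 5, 2]))
        assert data.label_order == (2, 5)
        assert data.class_counts == (2, 2)


class TestClassStatistics:
    def test_hand_case(self, hand_case):
        stats = compute_class_statistics(hand_case)
        # class means (1,0) and (1,2); two-point unbiased covariances
        np.testing.assert_allclose(stats.between_direction, [0.0, -2.0])
        np.testing.assert_allclose(stats.per_class_scatters[0], [[2, 0], [0, 0]])
        np.testing.assert_allclose(stats.per_class_scatters[1], [[0, 0], [0, 2]])
        assert stats.beta == 0.5
        np.testing.assert_allclose(stats.within_scatter, np.eye(2))

    def test_matches_textbook_covariance(self, gaussian_pair):
        stats = compute_class_statistics(gaussian_pair)
        y1 = gaussian_pair.class_matrix(1)
        np.testing.assert_allclose(
            stats.per_class_scatters[0], np.cov(y1.T, ddof=1), atol=1e-12
        )

    def test_balanced_modes_coincide(self, gaussian_pair):
        printed = compute_class_statistics(gaussian_pair, "as_printed")
        pooled = compute_class_statistics(gaussian_pair, "pooled")
        assert printed.beta == 0.5
        np.testing.assert_allclose(printed.within_scatter, pooled.within_scatter)

    def test_unbalanced_modes_differ(self, rng):
        x = rng.normal(size=(30, 4))
        labels = np.array([1] * 10 + [2] * 20)
        data = LabelledFeatures(x, labels)
        printed = compute_class_statistics(data, "as_printed")
        pooled = compute_class_statistics(data, "pooled")
        assert printed.beta == pytest.approx(19 / 28)
        # cross weighting: class-2 count weights the class-1 scatter
        expected = (19 / 28) * printed.per_class_scatters[0] + (
            9 / 28
        ) * printed.per_class_scatters[1]
        np.testing.assert_allclose(printed.within_scatter, expected)
        assert not np.allclose(printed.within_scatter, pooled.within_scatter)

    def test_identical_classes_zero_between(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        data = LabelledFeatures(np.vstack([pts, pts]), np.array([1, 1, 2, 2]))
        stats = compute_class_statistics(data)
        np.testing.assert_allclose(stats.between_direction, 0.0)

    def test_degenerate_class(self):
        data = LabelledFeatures(np.eye(3), np.array([1, 2, 2]))
        with pytest.raises(DegenerateClassError):
            compute_class_statistics(data)

    def test_between_scatter_rank_one(self, gaussian_pair):
        stats = compute_class_statistics(gaussian_pair)
        assert np.linalg.matrix_rank(stats.between_scatter) <= 1


class TestFisherCriterion:
    def test_orthogonal_direction_is_zero(self, rng):
        stats = ClassStatistics.from_scatter(
            np.array([1.0, 0.0]), oracles.random_spd(rng, 2)
        )
        assert fisher_criterion(np.array([0.0, 1.0]), stats) == 0.0

    def test_scale_invariance(self, rng):
        stats = ClassStatistics.from_scatter(
            rng.normal(size=5), oracles.random_spd(rng, 5)
        )
        d = rng.normal(size=5)
        assert fisher_criterion(2 * d, stats) == pytest.approx(
            fisher_criterion(d, stats), rel=1e-12
        )

    def test_identity_within_value(self):
        stats = ClassStatistics.from_scatter(np.array([3.0, 4.0]), np.eye(2))
        # R(s_b) = (s_b . s_b)^2 / (s_b . s_b) = 25
        assert fisher_criterion(np.array([3.0, 4.0]), stats) == pytest.approx(25.0)

    def test_zero_vector_rejected(self, rng):
        stats = ClassStatistics.from_scatter(np.ones(3), np.eye(3))
        with pytest.raises(ValidationError):
            fisher_criterion(np.zeros(3), stats)


class TestFirstDirection:
    def test_identity_within(self):
        s_b = np.zeros(6)
        s_b[-1] = 5.0
        stats = ClassStatistics.from_scatter(s_b, np.eye(6))
        d1, alpha1 = first_direction(stats)
        expected = np.zeros(6)
        expected[-1] = 1.0
        np.testing.assert_array_equal(d1, expected)
        assert alpha1 == pytest.approx(1 / 5)

    def test_matches_generalized_eigenproblem(self, rng):
        for _ in range(10):
            m = 7
            s_w = oracles.random_spd(rng, m)
            s_b = rng.normal(size=m)
            stats = ClassStatistics.from_scatter(s_b, s_w)
            d1, _ = first_direction(stats)
            ref = oracles.leading_generalized_eigvec(s_b, s_w)
            if ref @ d1 < 0:
                ref = -ref
            np.testing.assert_allclose(d1, ref, atol=1e-6)

    def test_monte_carlo_maximality(self, rng):
        m = 8
        s_w = oracles.random_spd(rng, m)
        s_b = rng.normal(size=m)
        stats = ClassStatistics.from_scatter(s_b, s_w)
        d1, _ = first_direction(stats)
        best = fisher_criterion(d1, stats)
        draws = rng.normal(size=(10_000, m))
        draws /= np.linalg.norm(draws, axis=1, keepdims=True)
        rivals = (s_b @ draws.T) ** 2 / np.einsum("ij,jk,ik->i", draws, s_w, draws)
        assert best >= rivals.max()

    def test_coincident_means(self):
        stats = ClassStatistics.from_scatter(np.zeros(3), np.eye(3))
        with pytest.raises(NoDiscriminantDirectionError):
            first_direction(stats)


class TestRecursion:
    def test_second_direction_matches_closed_form(self, rng):
        for _ in range(10):
            m = 6
            s_w = oracles.random_spd(rng, m)
            s_b = rng.normal(size=m)
            stats = ClassStatistics.from_scatter(s_b, s_w)
            basis = fit_basis_from_stats(stats, 2, ridge=0.0)
            d2_ref = oracles.closed_form_second_direction(s_b, s_w)
            if d2_ref @ basis.directions[1] < 0:
                d2_ref = -d2_ref
            np.testing.assert_allclose(basis.directions[1], d2_ref, atol=1e-8)

    def test_identity_within_exhausts_immediately(self):
        stats = ClassStatistics.from_scatter(np.array([1.0, 2.0, 2.0]), np.eye(3))
        basis = fit_basis_from_stats(stats, 1, ridge=0.0)
        with pytest.raises(SubspaceExhausted):
            next_direction(stats, basis, ridge=0.0)

    def test_constrained_maximality(self, rng):
        m = 6
        s_w = oracles.random_spd(rng, m)
        s_b = rng.normal(size=m)
        stats = ClassStatistics.from_scatter(s_b, s_w)
        basis = fit_basis_from_stats(stats, 4, ridge=0.0)
        for n in range(1, basis.n_directions):
            rivals = oracles.random_unit_in_complement(
                rng, basis.directions[:n], 10_000
            )
            rival_best = max(
                oracles.rayleigh(v, s_b, s_w) for v in rivals
            )
            own = fisher_criterion(basis.directions[n], stats)
            assert own >= rival_best * (1 - 1e-9)

    def test_orthogonality_across_directions(self, gaussian_pair):
        basis = fit_basis(gaussian_pair, 5, ridge=0.0)
        gram = basis.directions @ basis.directions.T
        np.testing.assert_allclose(gram, np.eye(basis.n_directions), atol=1e-8)


class TestFitBasis:
    def test_l1_is_classical_fisher(self, gaussian_pair):
        basis = fit_basis(gaussian_pair, 1, ridge=0.0)
        stats = compute_class_statistics(gaussian_pair)
        d1, _ = first_direction(stats)
        np.testing.assert_allclose(basis.directions[0], d1)

    def test_projection_rows_orthonormal(self, rng):
        data = LabelledFeatures(
            rng.normal(size=(50, 20)), np.repeat([1, 2], 25)
        )
        basis = fit_basis(data, 10)
        p = basis.projection
        np.testing.assert_allclose(p @ p.T, np.eye(p.shape[0]), atol=1e-8)

    def test_default_direction_count_is_ten(self, rng):
        data = LabelledFeatures(rng.normal(size=(60, 30)), np.repeat([1, 2], 30))
        assert fit_basis(data).n_directions == 10

    def test_truncation_warns(self):
        stats = ClassStatistics.from_scatter(np.array([1.0, 1.0]), np.eye(2))
        with pytest.warns(RuntimeWarning, match="exhausted"):
            basis = fit_basis_from_stats(stats, 5, ridge=0.0)
        assert basis.n_directions == 1

    def test_permutation_invariance(self, rng, gaussian_pair):
        basis = fit_basis(gaussian_pair, 3, ridge=0.0)
        perm = rng.permutation(gaussian_pair.n_samples)
        shuffled = LabelledFeatures(
            gaussian_pair.matrix[perm], gaussian_pair.labels[perm]
        )
        basis2 = fit_basis(shuffled, 3, ridge=0.0)
        np.testing.assert_allclose(basis.directions, basis2.directions, atol=1e-6)

    def test_isotropic_within_limit(self, rng):
        # S_W = sigma^2 I: single direction along the mean difference
        m = 5
        s_b = rng.normal(size=m)
        stats = ClassStatistics.from_scatter(s_b, 2.5 * np.eye(m))
        with pytest.warns(RuntimeWarning):
            basis = fit_basis_from_stats(stats, 3, ridge=0.0)
        assert basis.n_directions == 1
        np.testing.assert_allclose(
            basis.directions[0], s_b / np.linalg.norm(s_b), atol=1e-12
        )


class TestProject:
    def test_single_row_picks_coordinate(self):
        from fsda.core_da import DiscriminantBasis

        p = np.zeros((1, 4))
        p[0, 2] = 1.0
        basis = DiscriminantBasis(p, np.ones(1), np.ones(1), np.zeros((0, 0)))
        y = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(project(basis, y), [3.0])

    def test_zero_maps_to_zero(self, gaussian_pair):
        basis = fit_basis(gaussian_pair, 3)
        np.testing.assert_allclose(project(basis, np.zeros(8)), 0.0)

    def test_batch_equals_rowwise(self, rng, gaussian_pair):
        basis = fit_basis(gaussian_pair, 3)
        batch = rng.normal(size=(7, 8))
        rows = np.array([project(basis, row) for row in batch])
        np.testing.assert_array_equal(project(basis, batch), rows)

    def test_linearity(self, rng, gaussian_pair):
        basis = fit_basis(gaussian_pair, 3)
        y1, y2 = rng.normal(size=(2, 8))
        np.testing.assert_allclose(
            project(basis, 2.0 * y1 + 3.0 * y2),
            2.0 * project(basis, y1) + 3.0 * project(basis, y2),
            atol=1e-12,
        )

    def test_dimension_mismatch(self, gaussian_pair):
        basis = fit_basis(gaussian_pair, 2)
        with pytest.raises(ValidationError):
            project(basis, np.zeros(9))


def test_basis_roundtrip(tmp_path, gaussian_pair):
    basis = fit_basis(gaussian_pair, 4)
    path = tmp_path / "basis.npz"
    save_basis(path, basis)
    loaded = load_basis(path)
    np.testing.assert_array_equal(loaded.directions, basis.directions)
    np.testing.assert_array_equal(loaded.alphas, basis.alphas)
    assert loaded.within_mode == basis.within_mode
    assert loaded.ridge == basis.ridge
    assert loaded.label_order == basis.label_order
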