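"""Kernel construction, eigen-term identity, cluster-count selection,
kernel K-means optimality, screening entropy and composition summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cluster import KMeans

from mobiqc import (
    KernelSpec,
    cluster_composition,
    compute_kernel,
    eigen_terms,
    kernel_kmeans,
    kernel_quality,
    proportion_test,
    select_k,
)
from mobiqc.cluster import (
    EigenSelection,
    exhaustive_kernel_kmeans,
    objective_from_assignments,
)


class TestKernels:
    def test_gaussian_diagonal_is_one(self, rng):
        X = rng.standard_normal((10, 8))
        K = compute_kernel(X, KernelSpec("gaussian", sigma=4.0)).K
        assert np.allclose(np.diag(K), 1.0)

    def test_gaussian_at_characteristic_distance(self):
        sigma = 3.0
        x = np.zeros(4)
        y = np.zeros(4)
        y[0] = np.sqrt(2) * sigma  # ||x-y||^2 = 2 sigma^2
        K = compute_kernel(np.vstack([x, y]),
                           KernelSpec("gaussian", sigma=sigma)).K
        assert K[0, 1] == pytest.approx(np.exp(-1), abs=1e-12)

    def test_alternative_gaussian_convention(self):
        sigma = 3.0
        y = np.zeros(4)
        y[0] = sigma
        K = compute_kernel(np.vstack([np.zeros(4), y]),
                           KernelSpec("gaussian", sigma=sigma,
                                      convention="sigma2")).K
        assert K[0, 1] == pytest.approx(np.exp(-1), abs=1e-12)

    def test_linear_on_orthonormal_rows(self):
        X = np.eye(2)
        K = compute_kernel(X, KernelSpec("linear")).K
        assert np.allclose(K, np.eye(2))

    def test_polynomial_inhomogeneous_form(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0]])
        K = compute_kernel(X, KernelSpec("polynomial", degree=2)).K
        assert K[0, 1] == pytest.approx((0.0 + 1) ** 2)
        assert K[1, 1] == pytest.approx((4.0 + 1) ** 2)

    def test_gaussian_monotone_in_distance(self, rng):
        X = rng.standard_normal((15, 6))
        K = compute_kernel(X, KernelSpec("gaussian", sigma=2.0)).K
        D = ((X[:, None] - X[None]) ** 2).sum(-1)
        iu = np.triu_indices(15, 1)
        order = np.argsort(D[iu])
        assert np.all(np.diff(K[iu][order]) <= 1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("polynomial", degree=4)
        with pytest.raises(ValueError):
            KernelSpec("gaussian", sigma=-1.0)
        with pytest.raises(ValueError):
            KernelSpec("rbf")

    def test_non_finite_features_rejected(self):
        X = np.zeros((3, 2))
        X[1, 1] = np.inf
        with pytest.raises(ValueError):
            compute_kernel(X, KernelSpec("linear"))


class TestEigenTerms:
    def test_identity_kernel_total(self):
        sel = eigen_terms(np.eye(2))
        # w = (1/2, 1/2): w^T I w = 1/2
        assert sel.total == pytest.approx(0.5, abs=1e-12)

    def test_three_block_ones_kernel(self):
        K = np.kron(np.eye(3), np.ones((2, 2)))
        sel = eigen_terms(K)
        nonzero = sel.terms[np.abs(sel.terms) > 1e-12]
        assert len(nonzero) == 3
        assert np.allclose(nonzero, 1.0 / 9.0)

    @pytest.mark.parametrize("spec", [
        KernelSpec("linear"),
        KernelSpec("polynomial", degree=3),
        KernelSpec("gaussian", sigma=12.0),
    ])
    def test_identity_against_direct_quadratic_form(self, rng, spec):
        X = rng.standard_normal((8, 5))
        Km = compute_kernel(X, spec)
        sel = eigen_terms(Km)
        w = np.full(8, 1 / 8)
        direct = w @ Km.K @ w
        assert abs(sel.total - direct) <= 1e-8 * abs(direct)

    def test_terms_non_negative_for_psd_kernels(self, rng):
        X = rng.standard_normal((12, 4))
        sel = eigen_terms(compute_kernel(X, KernelSpec("gaussian", sigma=2.0)))
        assert np.all(sel.terms >= -1e-10)

    def test_asymmetric_matrix_rejected(self):
        K = np.array([[1.0, 0.5], [0.1, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            eigen_terms(K)


class TestSelectK:
    def test_three_block_kernel_selects_three(self):
        K = np.kron(np.eye(3), np.ones((2, 2)))
        assert select_k(eigen_terms(K)) == 3

    def test_largest_gap_on_hand_terms(self):
        sel = EigenSelection(np.array([10.0, 9.5, 0.1, 0.05]), np.ones(4),
                             np.array([10.0, 9.5, 0.1, 0.05]))
        assert select_k(sel) == 2

    def test_single_dominant_term(self):
        sel = EigenSelection(np.array([5.0, 0.0, 0.0]), np.ones(3),
                             np.array([5.0, 0.0, 0.0]))
        assert select_k(sel) == 1

    def test_all_equal_terms_warn_and_return_one(self):
        sel = EigenSelection(np.ones(4), np.ones(4), np.ones(4))
        with pytest.warns(UserWarning):
            assert select_k(sel) == 1

    def test_threshold_rule(self):
        sel = EigenSelection(np.array([10.0, 9.5, 0.1, 0.05]), np.ones(4),
                             np.array([10.0, 9.5, 0.1, 0.05]))
        assert select_k(sel, rule="threshold", tau=0.05) == 2
        assert select_k(sel, rule="threshold", tau=0.001) == 4

    def test_k_max_cap(self):
        terms = np.concatenate([np.linspace(20, 10, 15), [0.0]])
        sel = EigenSelection(terms, np.ones(16), terms)
        assert select_k(sel, k_max=10) <= 10


class TestKernelKMeans:
    def test_two_well_separated_pairs(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        Km = compute_kernel(X, KernelSpec("linear"))
        model = kernel_kmeans(Km, 2, n_init=20, seed=0)
        assert model.assignments[0] == model.assignments[1]
        assert model.assignments[2] == model.assignments[3]
        assert model.assignments[0] != model.assignments[2]
        _, best = exhaustive_kernel_kmeans(Km.K, 2)
        assert model.objective == pytest.approx(best, abs=1e-12)

    def test_identical_points_zero_objective(self):
        X = np.ones((5, 3))
        model = kernel_kmeans(compute_kernel(X, KernelSpec("linear")), 2,
                              n_init=5, seed=1)
        assert model.objective == pytest.approx(0.0, abs=1e-9)

    def test_k_equals_n_gives_singletons(self, rng):
        X = rng.standard_normal((6, 3))
        model = kernel_kmeans(compute_kernel(X, KernelSpec("linear")), 6,
                              n_init=10, seed=2)
        assert model.objective == pytest.approx(0.0, abs=1e-9)
        assert len(np.unique(model.assignments)) == 6

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((30, 4))
        Km = compute_kernel(X, KernelSpec("gaussian", sigma=2.0))
        m1 = kernel_kmeans(Km, 3, n_init=10, seed=42)
        m2 = kernel_kmeans(Km, 3, n_init=10, seed=42)
        assert np.array_equal(m1.assignments, m2.assignments)
        assert m1.best_restart == m2.best_restart

    def test_objective_consistent_with_assignments(self, rng):
        X = rng.standard_normal((25, 4))
        Km = compute_kernel(X, KernelSpec("polynomial", degree=2))
        model = kernel_kmeans(Km, 4, n_init=20, seed=3)
        assert model.objective == pytest.approx(
            objective_from_assignments(Km.K, model.assignments), abs=1e-8)
        assert len(np.unique(model.assignments)) == 4

    def test_linear_kernel_matches_euclidean_kmeans(self, rng):
        """With the linear kernel, the feature space is the input space, so
        the best objective matches scikit-learn K-means inertia."""
        X = rng.standard_normal((40, 3))
        Km = compute_kernel(X, KernelSpec("linear"))
        model = kernel_kmeans(Km, 3, n_init=50, seed=0)
        ref = KMeans(n_clusters=3, n_init=50, random_state=0).fit(X)
        assert model.objective == pytest.approx(ref.inertia_, rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           n=st.integers(4, 9),
           k=st.integers(2, 3))
    def test_multirestart_reaches_enumeration_optimum(self, seed, n, k):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 3))
        Km = compute_kernel(X, KernelSpec("gaussian", sigma=1.5))
        model = kernel_kmeans(Km, k, n_init=200, seed=seed)
        _, best = exhaustive_kernel_kmeans(Km.K, k)
        assert model.objective <= best + 1e-9


class TestKernelQuality:
    def test_constant_offdiagonal_entropy_zero(self):
        K = np.ones((4, 4))
        assert kernel_quality(K) == 0.0

    def test_two_value_offdiagonal_one_bit(self):
        K = np.eye(4)
        vals = [0.1, 0.9, 0.1, 0.9, 0.1, 0.9]
        iu = np.triu_indices(4, 1)
        K[iu] = vals
        K = K + K.T - np.diag(np.diag(K))
        assert kernel_quality(K) == pytest.approx(1.0)

    def test_uniform_offdiagonal_near_max(self, rng):
        n = 200
        K = np.ones((n, n))
        iu = np.triu_indices(n, 1)
        K[iu] = rng.uniform(0, 1, size=iu[0].size)
        K.T[iu] = K[iu]
        assert kernel_quality(K) > 0.95 * np.log2(32)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            kernel_quality(np.ones((2, 2)))


class TestCompositionAndProportions:
    def _model(self, assignments):
        from mobiqc.cluster import ClusterModel
        return ClusterModel(assignments=np.asarray(assignments),
                            k=len(set(assignments)), objective=0.0,
                            n_restarts=1, best_restart=0,
                            spec=KernelSpec("linear"))

    def test_headset_proportions_count_correctly(self):
        table = pd.DataFrame({
            "headset": ["A"] * 7 + ["B"] * 3,
            "condition": ["baseline"] * 10,
            "gender": ["F"] * 10,
        })
        comp = cluster_composition(self._model([0] * 10), table)
        props = comp["proportions"]
        a_share = props[(props.facet == "headset") & (props.level == "A")]
        assert a_share.proportion.iloc[0] == pytest.approx(0.7)

    def test_proportions_sum_to_one_per_facet(self, rng):
        table = pd.DataFrame({
            "headset": rng.choice(["A", "B", "C"], 60),
            "condition": rng.choice(["baseline", "piece_viewing"], 60),
            "gender": rng.choice(["F", "M"], 60),
        })
        comp = cluster_composition(self._model(rng.integers(0, 3, 60)), table)
        sums = comp["proportions"].groupby(["cluster", "facet"]).proportion.sum()
        assert np.allclose(sums, 1.0)

    def test_envelopes_bracket_mean(self, rng):
        n = 40
        psd = rng.uniform(size=(n, 4))
        table = pd.DataFrame(psd, columns=[f"f{i}" for i in range(4)])
        table["headset"] = "A"
        table["condition"] = "baseline"
        comp = cluster_composition(self._model(rng.integers(0, 2, n)), table,
                                   facets=("headset",))
        env = comp["envelopes"]
        assert np.all(env.p5 <= env["mean"] + 1e-12)
        assert np.all(env["mean"] <= env.p95 + 1e-12)

    def test_length_mismatch_rejected(self):
        table = pd.DataFrame({"headset": ["A", "B"]})
        with pytest.raises(ValueError):
            cluster_composition(self._model([0, 1, 1]), table)

    def test_proportion_test_null_exact(self):
        p, sig = proportion_test((50, 50), 0.5)
        assert p == pytest.approx(1.0)
        assert not sig

    def test_proportion_test_enriched_cluster(self):
        p, sig = proportion_test((90, 10), 0.21)
        assert sig and p < 1e-10

    def test_proportion_test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            proportion_test((0, 0), 0.5)
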