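"""SNF kernels, cross-diffusion, spectral clustering, dominance, survival."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from hfpef_pipeline import snf as sn


def _frame(X, ids=None):
    ids = ids or [f"s{i}" for i in range(len(X))]
    return pd.DataFrame(np.asarray(X, dtype=float), index=ids)


def _two_cluster_blocks(n=60, p=5, shift=2.0, seed=0, noise_second=False):
    rng = np.random.default_rng(seed)
    half = n // 2
    X1 = rng.normal(0, 1, (n, p))
    X1[:half] += shift
    if noise_second:
        X2 = rng.normal(0, 1, (n, p))
    else:
        X2 = rng.normal(0, 1, (n, p))
        X2[:half] += shift
    truth = [0] * half + [1] * (n - half)
    return _frame(X1), _frame(X2), truth


class TestBuildAffinity:
    def test_identical_samples_have_maximal_affinity(self):
        X = _frame([[0.0, 1.0], [0.0, 1.0], [5.0, 5.0], [9.0, 2.0],
                    [3.0, 7.0], [1.0, 4.0]])
        aff = sn.build_affinity(X, sn.SnfParams(K=2))
        assert aff.matrix[0, 1] == pytest.approx(1.0)

    def test_six_point_toy_matches_formula_oracle(self):
        """Brute-force recomputation of W(i,j)=exp(-d^2/(mu*eps))."""
        pts = np.array([0.0, 1.0, 2.5, 4.0, 7.0, 11.0])
        X = _frame(pts[:, None])
        K, mu = 2, 0.5
        aff = sn.build_affinity(X, sn.SnfParams(K=K, mu=mu))
        z = (pts - pts.mean()) / pts.std()
        D = np.abs(z[:, None] - z[None, :])
        mean_knn = np.array([np.sort(row)[1:K + 1].mean() for row in D])
        for i in range(6):
            for j in range(6):
                eps = (mean_knn[i] + mean_knn[j] + D[i, j]) / 3
                expect = np.exp(-D[i, j] ** 2 / (mu * eps))
                assert aff.matrix[i, j] == pytest.approx(expect, rel=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 4))
        ids = [f"s{i}" for i in range(12)]
        aff = sn.build_affinity(_frame(X, ids), sn.SnfParams(K=3))
        perm = rng.permutation(12)
        aff_p = sn.build_affinity(_frame(X[perm], [ids[i] for i in perm]),
                                  sn.SnfParams(K=3))
        assert np.allclose(aff_p.matrix, aff.matrix[np.ix_(perm, perm)])

    def test_scale_invariance_after_standardization(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 6))
        a1 = sn.build_affinity(_frame(X), sn.SnfParams(K=4))
        a2 = sn.build_affinity(_frame(X * 37.5), sn.SnfParams(K=4))
        assert np.allclose(a1.matrix, a2.matrix)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="<= K"):
            sn.build_affinity(_frame(np.eye(3)), sn.SnfParams(K=5))

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            aff = sn.build_affinity(_frame(X), sn.SnfParams(K=3))
        assert np.all(np.isfinite(aff.matrix))


class TestKernels:
    def test_full_kernel_row_stochastic_with_half_diagonal(self):
        rng = np.random.default_rng(4)
        W = rng.uniform(0.1, 1, (8, 8))
        W = (W + W.T) / 2
        P = sn._full_kernel(W)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(np.diag(P), 0.5)

    def test_sparse_kernel_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        W = rng.uniform(0.1, 1, (10, 10))
        W = (W + W.T) / 2
        S = sn._sparse_kernel(W, K=3)
        assert np.allclose(S.sum(axis=1), 1.0, atol=1e-9)
        assert ((S > 0).sum(axis=1) <= 3).all()


class TestFuse:
    def test_identical_modalities_stay_identical(self):
        X1, _, _ = _two_cluster_blocks(n=30)
        a = sn.build_affinity(X1, sn.SnfParams(K=5, t=5))
        fused = sn.fuse([a, sn.AffinityMatrix(a.matrix.copy(), a.index)],
                        sn.SnfParams(K=5, t=5))
        # each P_v sees the same "other" kernel, so the average equals either
        assert np.allclose(fused.matrix, fused.matrix.T)
        assert np.all(np.isfinite(fused.matrix))

    def test_index_mismatch_rejected(self):
        X1, X2, _ = _two_cluster_blocks(n=20)
        a1 = sn.build_affinity(X1, sn.SnfParams(K=4))
        X2.index = [f"t{i}" for i in range(20)]
        a2 = sn.build_affinity(X2, sn.SnfParams(K=4))
        with pytest.raises(ValueError, match="mismatch"):
            sn.fuse([a1, a2], sn.SnfParams(K=4))

    def test_fewer_than_two_modalities_rejected(self):
        X1, _, _ = _two_cluster_blocks(n=20)
        a1 = sn.build_affinity(X1, sn.SnfParams(K=4))
        with pytest.raises(ValueError):
            sn.fuse([a1], sn.SnfParams(K=4))

    def test_planted_two_cluster_recovery(self):
        """Two modalities from the same 2-cluster structure: fused spectral
        clustering recovers the planted labels exactly."""
        X1, X2, truth = _two_cluster_blocks(n=60, shift=2.0, seed=10)
        params = sn.SnfParams(K=10, t=10)
        fused = sn.fuse([sn.build_affinity(X1, params),
                         sn.build_affinity(X2, params)], params)
        asg = sn.spectral_cluster(fused, 2, params, seed=0)
        pred = [asg.labels[i] for i in fused.index]
        assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)

    def test_noise_modality_does_not_destroy_signal(self):
        """One informative + one pure-noise modality: fused clustering still
        recovers the planted 2-cluster structure (ARI >= 0.9)."""
        X1, X2, truth = _two_cluster_blocks(n=60, shift=3.0, seed=11,
                                            noise_second=True)
        params = sn.SnfParams(K=10, t=10)
        fused = sn.fuse([sn.build_affinity(X1, params),
                         sn.build_affinity(X2, params)], params)
        asg = sn.spectral_cluster(fused, 2, params, seed=0)
        pred = [asg.labels[i] for i in fused.index]
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_fused_matrix_properties(self):
        X1, X2, _ = _two_cluster_blocks(n=40)
        params = sn.SnfParams(K=8, t=5)
        fused = sn.fuse([sn.build_affinity(X1, params),
                         sn.build_affinity(X2, params)], params)
        M = fused.matrix
        assert np.allclose(M, M.T)
        assert (M >= -1e-12).all() and np.all(np.isfinite(M))
        # the final symmetrized average stays near row-stochastic
        assert np.allclose(M.sum(axis=1), 1.0, atol=0.05)


class TestSpectralCluster:
    def _block_affinity(self, sizes, within=1.0, between=0.0):
        n = sum(sizes)
        M = np.full((n, n), between)
        start = 0
        for s in sizes:
            M[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(M, 1.0)
        return sn.AffinityMatrix(M, [f"s{i}" for i in range(n)])

    def test_exact_two_block_recovery(self):
        aff = self._block_affinity([6, 6], between=0.01)
        asg = sn.spectral_cluster(aff, 2, seed=0)
        labs = [asg.labels[f"s{i}"] for i in range(12)]
        assert len(set(labs[:6])) == 1 and len(set(labs[6:])) == 1
        assert labs[0] != labs[6]

    def test_k_equal_n_rejected(self):
        aff = self._block_affinity([4, 4], between=0.1)
        with pytest.raises(ValueError, match="outside"):
            sn.spectral_cluster(aff, 8)

    def test_disconnected_components_exceeding_k(self):
        aff = self._block_affinity([4, 4, 4], between=0.0)
        with pytest.raises(ValueError, match="3 connected components"):
            sn.spectral_cluster(aff, 2)

    def test_eigengap_detects_block_count(self):
        aff = self._block_affinity([5, 5, 5], between=0.02)
        assert sn.eigengap_k(aff.matrix, (2, 8)) == 3

    def test_cluster_sizes_sum_to_n(self):
        aff = self._block_affinity([7, 5], between=0.05)
        asg = sn.spectral_cluster(aff, 2, seed=0)
        assert sum(asg.sizes().values()) == 12


class TestModalityDominance:
    def test_single_modality_all_ones(self):
        X1, _, _ = _two_cluster_blocks(n=20)
        a = sn.build_affinity(X1, sn.SnfParams(K=4))
        asg = sn.ClusterAssignment({i: 1 for i in a.index}, k=1)
        dom = sn.modality_dominance({"only": a}, asg)
        assert (dom["only"] == 1.0).all()

    def test_identical_in_one_modality_dominates(self):
        """Cluster members identical in modality A, random in B: A dominant
        for every member."""
        rng = np.random.default_rng(6)
        n = 12
        XA = rng.normal(size=(n, 4))
        XA[:6] = XA[0]                      # cluster 1 identical in A
        XB = rng.normal(size=(n, 4))
        pA = sn.build_affinity(_frame(XA + rng.normal(0, 1e-9, XA.shape)),
                               sn.SnfParams(K=3))
        pB = sn.build_affinity(_frame(XB), sn.SnfParams(K=3))
        asg = sn.ClusterAssignment(
            {f"s{i}": 1 if i < 6 else 2 for i in range(n)}, k=2)
        dom = sn.modality_dominance({"A": pA, "B": pB}, asg)
        assert dom.loc[1, "A"] == 1.0

    def test_fractions_sum_to_one_and_singleton_missing(self):
        rng = np.random.default_rng(7)
        X = _frame(rng.normal(size=(9, 3)))
        a = sn.build_affinity(X, sn.SnfParams(K=2))
        labels = {f"s{i}": 1 for i in range(8)}
        labels["s8"] = 2                    # singleton cluster
        asg = sn.ClusterAssignment(labels, k=2)
        dom = sn.modality_dominance({"A": a, "B": a}, asg)
        assert dom.loc[1].sum() == pytest.approx(1.0)
        assert dom.loc[2].isna().all()


class TestKmByCluster:
    def _asg(self, ids, cluster=1):
        return sn.ClusterAssignment({i: cluster for i in ids}, k=cluster)

    def test_no_deaths_survival_stays_one(self):
        ids = [f"p{i}" for i in range(5)]
        fu = {i: (10.0, False) for i in ids}
        km = sn.km_by_cluster(self._asg(ids), fu)
        assert np.allclose(km[1]["survival"], 1.0)
        assert km[1]["mortality_fraction"] == 0.0

    def test_all_die_at_one(self):
        ids = [f"p{i}" for i in range(4)]
        fu = {i: (1.0, True) for i in ids}
        km = sn.km_by_cluster(self._asg(ids), fu)
        assert km[1]["survival"][-1] == pytest.approx(0.0)

    def test_five_subject_worked_example_with_censoring(self):
        """Deaths at 1,2,4,5; censoring at 3: S = .8, .6, .6, .3, 0."""
        ids = [f"p{i}" for i in range(5)]
        fu = {"p0": (1.0, True), "p1": (2.0, True), "p2": (3.0, False),
              "p3": (4.0, True), "p4": (5.0, True)}
        km = sn.km_by_cluster(self._asg(ids), fu)
        sf = dict(zip(km[1]["times"], km[1]["survival"]))
        assert sf[1.0] == pytest.approx(0.8)
        assert sf[2.0] == pytest.approx(0.6)
        assert sf[3.0] == pytest.approx(0.6)
        assert sf[4.0] == pytest.approx(0.3)
        assert sf[5.0] == pytest.approx(0.0)

    def test_survival_non_increasing_in_unit_interval(self):
        rng = np.random.default_rng(8)
        ids = [f"p{i}" for i in range(40)]
        fu = {i: (float(rng.exponential(5)), bool(rng.random() < 0.6))
              for i in ids}
        km = sn.km_by_cluster(self._asg(ids), fu)
        s = km[1]["survival"]
        assert ((s >= 0) & (s <= 1)).all()
        assert (np.diff(s) <= 1e-12).all()
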