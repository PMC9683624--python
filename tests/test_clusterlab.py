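import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdconnectome import (
    ClusterAssignment,
    GRID_PRESETS,
    MCLConfig,
    ParamGrid,
    SimilarityMatrix,
    SolverConfig,
    jaccard_clustering_similarity,
    mcl,
    run_sweep,
    spectral_cluster,
)
from rdconnectome.netgen import generate_surrogate
from rdconnectome.stability import gm_params_for


def _block_matrix(sizes, within=1.0, between=0.0, noise=0.0, seed=0):
    n = sum(sizes)
    M = np.full((n, n), between, dtype=float)
    start = 0
    truth = []
    for s in sizes:
        M[start:start + s, start:start + s] = within
        truth.extend([len(truth) and truth[-1] + 1 or 0] * 0)  # placeholder
        start += s
    labels = np.concatenate([[i] * s for i, s in enumerate(sizes)])
    if noise:
        rng = np.random.default_rng(seed)
        N = rng.normal(0, noise, (n, n))
        M = M + (N + N.T) / 2
        np.fill_diagonal(M, within)
        M = np.clip(M, 0, 1)
    M = (M + M.T) / 2
    return SimilarityMatrix(matrix=M, nodes=list(range(n)), statistic="test"), labels


class TestSpectral:
    def test_exact_two_blocks_recovered(self):
        sim, truth = _block_matrix([4, 4])
        ca = spectral_cluster(sim, k=2)
        got = np.array([ca.labels[i] for i in range(8)])
        assert len(set(got[:4])) == 1 and len(set(got[4:])) == 1
        assert got[0] != got[-1]

    def test_partition_invariant_under_node_permutation(self):
        sim, _ = _block_matrix([3, 3, 3], noise=0.02, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(9)
        sim_p = SimilarityMatrix(matrix=sim.matrix[np.ix_(perm, perm)],
                                 nodes=[sim.nodes[i] for i in perm], statistic="test")
        a = spectral_cluster(sim, k=3)
        b = spectral_cluster(sim_p, k=3)
        assert {frozenset(c) for c in a.clusters()} == \
               {frozenset(c) for c in b.clusters()}

    def test_noisy_three_blocks_recovered_across_seeds(self):
        for seed in range(20):
            sim, truth = _block_matrix([5, 5, 5], noise=0.05, seed=seed)
            ca = spectral_cluster(sim, k=3, seed=seed)
            blocks = [frozenset(range(0, 5)), frozenset(range(5, 10)),
                      frozenset(range(10, 15))]
            assert {frozenset(c) for c in ca.clusters()} == set(blocks)

    def test_eigengap_auto_k(self):
        sim, _ = _block_matrix([6, 6], noise=0.02, seed=1)
        ca = spectral_cluster(sim, k="auto")
        assert ca.n_clusters == 2

    def test_k_larger_than_n_rejected(self):
        sim, _ = _block_matrix([3, 3])
        with pytest.raises(ValueError):
            spectral_cluster(sim, k=7)


class TestMCL:
    def test_two_disconnected_triangles(self):
        M = np.zeros((6, 6))
        for blk in ([0, 1, 2], [3, 4, 5]):
            for i in blk:
                for j in blk:
                    M[i, j] = 1.0
        ca = mcl(M, MCLConfig())
        assert ca.n_clusters == 2
        assert {frozenset(c) for c in ca.clusters()} == \
               {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_identity_with_loop_gain_gives_singletons(self):
        ca = mcl(np.eye(7), MCLConfig(loop_gain=0.5))
        assert ca.n_clusters == 7

    def test_output_is_partition(self, fixture_connectome):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (10, 10))
        ca = mcl((X + X.T) / 2, MCLConfig(loop_gain=0.1))
        assert set(ca.labels) == set(range(10))
        assert sum(len(c) for c in ca.clusters()) == 10

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            mcl(-np.ones((3, 3)), MCLConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCLConfig(inflation=1.0)
        with pytest.raises(ValueError):
            MCLConfig(zero_threshold=-1)


class TestJaccard:
    def test_identical_partitions_score_one(self):
        A = ClusterAssignment.from_clusters([{1, 2, 5}, {3, 4}])
        assert jaccard_clustering_similarity(A, A) == 1.0

    def test_merge_example(self):
        A = ClusterAssignment.from_clusters([{1, 2}, {3, 4}])
        B = ClusterAssignment.from_clusters([{1, 2, 3, 4}])
        assert jaccard_clustering_similarity(A, B) == pytest.approx(0.5)

    def test_singleton_example(self):
        A = ClusterAssignment.from_clusters([{1, 2, 3, 4}])
        B = ClusterAssignment.from_clusters([{1}, {2}, {3}, {4}])
        assert jaccard_clustering_similarity(A, B) == pytest.approx(0.25)

    def test_mismatched_node_sets_rejected(self):
        A = ClusterAssignment.from_clusters([{1, 2}])
        B = ClusterAssignment.from_clusters([{1, 3}])
        with pytest.raises(ValueError):
            jaccard_clustering_similarity(A, B)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_one_iff_identical(self, seed):
        rng = np.random.default_rng(seed)
        nodes = list(range(10))
        la = {n: int(rng.integers(3)) for n in nodes}
        lb = {n: int(rng.integers(3)) for n in nodes}
        A = ClusterAssignment(labels=la)
        B = ClusterAssignment(labels=lb)
        ab = jaccard_clustering_similarity(A, B)
        assert ab == pytest.approx(jaccard_clustering_similarity(B, A))
        same = {frozenset(c) for c in A.clusters()} == \
               {frozenset(c) for c in B.clusters()}
        assert (ab == pytest.approx(1.0)) == same


class TestParamGrid:
    @pytest.mark.parametrize(
        "preset,count",
        [("gm_2param", 16), ("gm_4param", 256), ("mm_540", 540), ("mm_375", 375)],
    )
    def test_published_sweep_sizes(self, preset, count):
        assert GRID_PRESETS[preset].n_combinations == count

    def test_single_value_axis(self):
        g = ParamGrid({"x": (1.0, 1.0, 0.5)})
        assert g.n_combinations == 1
        assert list(g) == [{"x": 1.0}]

    def test_inclusive_endpoints(self):
        g = ParamGrid({"rateA": (0.004, 0.016, 0.004)})
        np.testing.assert_allclose(g.values("rateA"), [0.004, 0.008, 0.012, 0.016])

    def test_index_roundtrip_bijection(self):
        g = GRID_PRESETS["mm_540"]
        for i in [0, 1, 17, 539]:
            assert g.index_of(g.combination(i)) == i
        combos = list(g)
        assert len(combos) == 540
        assert g.combination(0) == combos[0]
        assert g.combination(539) == combos[-1]

    def test_lexicographic_order_last_axis_fastest(self):
        g = ParamGrid({"a": (0, 1, 1), "b": (0, 2, 1)})
        assert [c["b"] for c in list(g)[:3]] == [0.0, 1.0, 2.0]
        assert [c["a"] for c in list(g)[:3]] == [0.0, 0.0, 0.0]


class TestSweep:
    def test_small_sweep_end_to_end(self):
        """A 4-combination GM sweep on a small network produces coherent
        artifacts: averaged matrix = mean, unit-diagonal symmetric
        clustering-similarity matrix."""
        c = generate_surrogate("erdos_renyi", n_nodes=6, p=0.6, seed=5)
        grid = ParamGrid({"muA": (0.018, 0.022, 0.004), "sigmaA": (0.001, 0.002, 0.001)})
        base = gm_params_for(0.001, 0.02)
        solver = SolverConfig(method="rk4", dt=2.0, n_steps=800, seed=0, v_floor=1e-9)
        init = np.vstack([np.linspace(0.4, 0.8, 6), np.full(6, 0.3)])
        res = run_sweep(grid, lambda p: dataclasses.replace(base, **p),
                        c, init, solver, clustering="spectral", k=2)
        assert len(res.combinations) == 4
        np.testing.assert_allclose(
            res.averaged.matrix, np.mean([m.matrix for m in res.matrices], axis=0)
        )
        S = res.clustering_similarity
        np.testing.assert_allclose(S, S.T)
        np.testing.assert_allclose(np.diag(S), 1.0)
        assert ((0 <= S) & (S <= 1 + 1e-12)).all()

    def test_failed_combinations_excluded_not_fatal(self):
        c = generate_surrogate("erdos_renyi", n_nodes=5, p=0.5, seed=1)
        grid = ParamGrid({"muI": (0.0, 0.01, 0.01)})  # muI=0 is invalid
        base = gm_params_for(0.001, 0.02)
        solver = SolverConfig(method="rk4", dt=2.0, n_steps=400, v_floor=1e-9)
        init = np.vstack([np.linspace(0.4, 0.8, 5), np.full(5, 0.3)])
        with pytest.warns(UserWarning, match="excluded"):
            res = run_sweep(grid, lambda p: dataclasses.replace(base, **p),
                            c, init, solver, clustering="spectral", k=2)
        assert len(res.failed) == 1
        assert len(res.combinations) == 1
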