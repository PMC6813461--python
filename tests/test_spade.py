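"""SPADE clustering: density, downsampling, agglomeration, MST, upsampling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cytoforge import spade
from cytoforge.errors import DomainError

from conftest import make_matrix


def _tm(values, markers=None):
    """Transformed EventMatrix helper (density etc. expect transformed data)."""
    m = make_matrix(values, markers=markers, transform="arcsinh", cofactor=5.0)
    return m


class TestDensity:
    def test_two_identical_cells_have_density_two(self):
        m = _tm([[1.0, 2.0], [1.0, 2.0]])
        d = spade.estimate_density(m, ["M0", "M1"])
        np.testing.assert_array_equal(d.density, [2.0, 2.0])

    def test_dense_blob_beats_sparse_spread(self, rng):
        blob = rng.normal(0.0, 0.1, size=(500, 3))
        spread = rng.normal(4.0, 3.0, size=(200, 3))
        m = _tm(np.vstack([blob, spread]))
        d = spade.estimate_density(m, ["M0", "M1", "M2"], seed=0)
        assert d.density[:500].mean() > d.density[500:].mean()

    def test_invariant_under_marker_permutation(self, rng):
        X = rng.normal(size=(300, 4))
        a = spade.estimate_density(_tm(X), ["M0", "M1", "M2", "M3"], seed=1)
        b = spade.estimate_density(_tm(X[:, ::-1]), ["M0", "M1", "M2", "M3"], seed=1)
        np.testing.assert_array_equal(a.density, b.density)

    def test_needs_two_cells(self):
        with pytest.raises(DomainError):
            spade.estimate_density(_tm([[1.0]]), ["M0"])


class TestDownsample:
    def test_target_one_retains_everything(self, rng):
        m = _tm(rng.normal(size=(200, 2)))
        d = spade.estimate_density(m, ["M0", "M1"], seed=0)
        sub, idx = spade.downsample(m, d, 1.0, seed=1)
        assert sub.n_cells == 200 and len(idx) == 200

    def test_five_percent_target_on_bimodal_cells(self, rng):
        blob = rng.normal(0.0, 0.15, size=(15_000, 3))
        spread = rng.normal(4.0, 2.0, size=(5_000, 3))
        m = _tm(np.vstack([blob, spread]))
        d = spade.estimate_density(m, ["M0", "M1", "M2"], seed=2)
        sub, idx = spade.downsample(m, d, 0.05, seed=3)
        frac = sub.n_cells / m.n_cells
        assert 0.045 <= frac <= 0.055
        # density equalization: retained cells are less unequal in density
        assert np.var(np.log(d.density[idx])) < np.var(np.log(d.density))
        # Gini of the retained set's own local density (same radius) drops:
        # the dense blob is thinned, so the surviving cloud is near-uniform
        from scipy.spatial.distance import cdist

        kept = m.values[idx]
        dens_kept = (cdist(kept, kept, metric="cityblock") <= d.radius).sum(axis=1).astype(float)

        def gini(x):
            x = np.sort(x)
            n = len(x)
            return float((2 * np.arange(1, n + 1) - n - 1) @ x / (n * x.sum()))

        assert gini(dens_kept) < gini(d.density)

    def test_reproducible_and_validated(self, rng):
        m = _tm(rng.normal(size=(500, 2)))
        d = spade.estimate_density(m, ["M0", "M1"], seed=0)
        _, i1 = spade.downsample(m, d, 0.2, seed=9)
        _, i2 = spade.downsample(m, d, 0.2, seed=9)
        np.testing.assert_array_equal(i1, i2)
        with pytest.raises(DomainError):
            spade.downsample(m, d, 0.0, seed=0)


class TestCluster:
    def test_separable_blobs_recovered_exactly(self, rng):
        a = rng.normal(0.0, 0.5, size=(100, 4))
        b = rng.normal(10.0, 0.5, size=(80, 4))  # 20-sigma separation
        m = _tm(np.vstack([a, b]))
        medians, assign = spade.cluster(m, ["M0", "M1", "M2", "M3"], k=2)
        assert len(set(assign[:100])) == 1 and len(set(assign[100:])) == 1
        assert assign[0] != assign[-1]

    def test_k_equals_cell_count_gives_singletons(self, rng):
        X = rng.normal(size=(12, 3))
        m = _tm(X)
        medians, assign = spade.cluster(m, ["M0", "M1", "M2"], k=12)
        assert len(np.unique(assign)) == 12
        for cid, row in medians.iterrows():
            np.testing.assert_allclose(row.to_numpy(), X[assign == cid][0])

    def test_k_larger_than_cells_rejected(self, rng):
        with pytest.raises(DomainError):
            spade.cluster(_tm(rng.normal(size=(5, 2))), ["M0", "M1"], k=6)


def _brute_force_mst_weight(D: np.ndarray) -> float:
    """Exhaustive minimum over all spanning trees via Pruefer sequences."""
    n = D.shape[0]
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        seq_list = list(seq)
        weight = 0.0
        deg = degree[:]
        ptr_nodes = sorted(range(n))
        import heapq

        leaves = [v for v in range(n) if deg[v] == 1]
        heapq.heapify(leaves)
        for v in seq_list:
            leaf = heapq.heappop(leaves)
            weight += D[leaf, v]
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(leaves, v)
        u = heapq.heappop(leaves)
        w = heapq.heappop(leaves)
        weight += D[u, w]
        best = min(best, weight)
    return best


class TestMst:
    def test_collinear_points_exclude_long_edge(self):
        med = pd.DataFrame({"M0": [0.0, 1.0, 10.0]}, index=[1, 2, 3])
        edges = spade.build_mst(med)
        pairs = {tuple(sorted(e[:2])) for e in edges}
        assert pairs == {(1, 2), (2, 3)}

    @pytest.mark.parametrize("k", [4, 6, 8])
    def test_weight_matches_exhaustive_minimum(self, k, rng):
        med = pd.DataFrame(rng.normal(size=(k, 3)), index=range(1, k + 1), columns=["M0", "M1", "M2"])
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(med.to_numpy(), metric="cityblock"))
        edges = spade.build_mst(med)
        assert len(edges) == k - 1
        total = sum(e[2] for e in edges)
        assert total == pytest.approx(_brute_force_mst_weight(D), rel=1e-9)

    def test_tree_property_for_random_k(self, rng):
        for k in (10, 37, 100):
            med = pd.DataFrame(rng.normal(size=(k, 2)), index=range(1, k + 1), columns=["M0", "M1"])
            edges = spade.build_mst(med)
            assert len(edges) == k - 1
            # connectivity via union-find
            parent = list(range(k + 1))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b, _ in edges:
                parent[find(a)] = find(b)
            assert len({find(c) for c in range(1, k + 1)}) == 1

    def test_duplicate_ids_rejected(self):
        med = pd.DataFrame({"M0": [0.0, 1.0]}, index=[1, 1])
        with pytest.raises(DomainError):
            spade.build_mst(med)


class TestUpsample:
    def test_cell_equal_to_median_goes_there(self):
        med = pd.DataFrame({"M0": [0.0, 5.0]}, index=[1, 2])
        m = _tm([[5.0]])
        assert spade.upsample(m, med, ["M0"])[0] == 2

    def test_equidistant_tie_goes_to_lower_id(self):
        med = pd.DataFrame({"M0": [3.0, 7.0]}, index=[3, 7])
        m = _tm([[5.0]])
        assert spade.upsample(m, med, ["M0"])[0] == 3

    def test_downsampled_cells_keep_their_cluster(self, rng):
        a = rng.normal(0.0, 0.4, size=(300, 3))
        b = rng.normal(8.0, 0.4, size=(300, 3))
        m = _tm(np.vstack([a, b]))
        markers = ["M0", "M1", "M2"]
        d = spade.estimate_density(m, markers, seed=0)
        sub, idx = spade.downsample(m, d, 0.3, seed=1)
        medians, assign_sub = spade.cluster(sub, markers, k=2)
        assign_full = spade.upsample(m, medians, markers)
        np.testing.assert_array_equal(assign_full[idx], assign_sub)


class TestAbundance:
    def test_single_cluster_is_all_ones(self):
        a = spade.abundance_table(np.ones(6, dtype=int), np.array(["s1"] * 3 + ["s2"] * 3), k=1)
        assert (a.loc[1] == 1.0).all()

    def test_thirty_seventy_split(self):
        assign = np.array([1] * 30 + [2] * 70)
        a = spade.abundance_table(assign, np.array(["s"] * 100), k=2)
        assert a.loc[1, "s"] == pytest.approx(0.3)
        assert a.loc[2, "s"] == pytest.approx(0.7)

    def test_columns_sum_to_one_and_empty_clusters_kept(self, rng):
        assign = rng.integers(1, 5, size=400)  # cluster 5 never appears
        samples = rng.choice(["a", "b", "c"], size=400)
        a = spade.abundance_table(assign, samples, k=5)
        np.testing.assert_allclose(a.sum(axis=0), 1.0, atol=1e-12)
        assert (a.loc[5] == 0).all()


class TestDeterminism:
    def test_identical_seeds_identical_tree(self, small_cohort, panel):
        kw = dict(markers=panel.subset("annotation9"), k=10, target_fraction=0.2, seed=99)
        t1 = spade.run_spade(small_cohort["transformed"][:4], **kw)
        t2 = spade.run_spade(small_cohort["transformed"][:4], **kw)
        np.testing.assert_array_equal(t1.assignment, t2.assignment)
        assert t1.mst_edges == t2.mst_edges
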