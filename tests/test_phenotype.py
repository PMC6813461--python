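"""Categorical phenotyping: percentile ranges, five-level binning, ordering, annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage

from cytoforge import phenotype
from cytoforge.errors import RuleError
from cytoforge.spade import SpadeTree

from conftest import make_matrix


def _tree_from_medians(mean_medians: pd.DataFrame) -> SpadeTree:
    """Build a minimal SpadeTree whose per-(cluster, sample) medians equal the
    given cluster x marker table for a single pseudo-sample."""
    med = mean_medians.copy()
    med.index = pd.MultiIndex.from_product([med.index, ["s1"]], names=["cluster", "sample"])
    k = mean_medians.index.max()
    return SpadeTree(
        k=int(k),
        assignment=np.asarray(mean_medians.index),
        cell_sample=np.array(["s1"] * len(mean_medians)),
        medians=med,
        pooled_medians=mean_medians,
        pooled_medians_all=mean_medians,
        mst_edges=[],
        markers=list(mean_medians.columns),
        sample_order=["s1"],
    )


class TestMarkerRanges:
    def test_constant_marker_degenerates(self):
        m = make_matrix(np.full((50, 1), 3.3), transform="arcsinh", cofactor=5.0)
        r = phenotype.marker_ranges(m)
        assert r.loc["M0", "p5"] == r.loc["M0", "p95"] == 3.3

    def test_linear_interpolation_quantiles(self):
        m = make_matrix(np.arange(1.0, 101.0)[:, None], transform="arcsinh", cofactor=5.0)
        r = phenotype.marker_ranges(m)
        assert r.loc["M0", "p5"] == pytest.approx(5.95)
        assert r.loc["M0", "p95"] == pytest.approx(95.05)

    def test_invariant_to_cell_order(self, rng):
        X = rng.normal(size=(200, 3))
        a = phenotype.marker_ranges(make_matrix(X, transform="arcsinh", cofactor=5.0))
        b = phenotype.marker_ranges(make_matrix(X[::-1], transform="arcsinh", cofactor=5.0))
        pd.testing.assert_frame_equal(a, b)


class TestCategorize:
    @pytest.fixture()
    def ranges(self):
        return pd.DataFrame({"p5": [0.0], "p95": [10.0]}, index=["M0"])

    @pytest.mark.parametrize(
        "value,category",
        [(-1.0, 0), (0.0, 0), (1.9, 0), (2.0, 1), (4.0, 2), (7.9, 3), (8.0, 4), (10.0, 4), (12.0, 4)],
    )
    def test_bin_arithmetic(self, ranges, value, category):
        tree = _tree_from_medians(pd.DataFrame({"M0": [value]}, index=[1]))
        cats = phenotype.categorize(tree, ranges)
        assert cats.loc[1, "M0"] == category

    def test_matches_direct_bin_oracle_on_random_fixtures(self, rng):
        for _ in range(20):
            p5, width = rng.normal(), rng.uniform(0.5, 3.0)
            p95 = p5 + width
            vals = rng.uniform(p5 - 1, p95 + 1, size=8)
            ranges = pd.DataFrame({"p5": [p5], "p95": [p95]}, index=["M0"])
            tree = _tree_from_medians(pd.DataFrame({"M0": vals}, index=range(1, 9)))
            cats = phenotype.categorize(tree, ranges)["M0"].to_numpy()
            edges = p5 + np.arange(1, 5) * (p95 - p5) / 5
            expected = np.searchsorted(edges, vals, side="right")
            np.testing.assert_array_equal(cats, expected)

    def test_monotone_in_expression(self, rng):
        ranges = pd.DataFrame({"p5": [0.0], "p95": [5.0]}, index=["M0"])
        vals = np.sort(rng.uniform(-1, 6, size=30))
        tree = _tree_from_medians(pd.DataFrame({"M0": vals}, index=range(1, 31)))
        cats = phenotype.categorize(tree, ranges)["M0"].to_numpy()
        assert (np.diff(cats) >= 0).all()

    def test_mean_excludes_samples_without_cells(self):
        # cluster 1 has a median only in sample s1; the mean must not dilute it
        med = pd.DataFrame(
            {"M0": [9.0, 1.0, 1.0]},
            index=pd.MultiIndex.from_tuples(
                [(1, "s1"), (2, "s1"), (2, "s2")], names=["cluster", "sample"]
            ),
        )
        tree = SpadeTree(
            k=2, assignment=np.array([1, 2]), cell_sample=np.array(["s1", "s2"]),
            medians=med, pooled_medians=pd.DataFrame({"M0": [9.0, 1.0]}, index=[1, 2]),
            pooled_medians_all=pd.DataFrame({"M0": [9.0, 1.0]}, index=[1, 2]),
            mst_edges=[], markers=["M0"], sample_order=["s1", "s2"],
        )
        ranges = pd.DataFrame({"p5": [0.0], "p95": [10.0]}, index=["M0"])
        cats = phenotype.categorize(tree, ranges)
        assert cats.loc[1, "M0"] == 4  # 9.0, not the diluted mean


class TestOrderHeatmap:
    def test_identical_clusters_adjacent_and_orders_are_permutations(self, rng):
        cats = pd.DataFrame(
            rng.integers(0, 5, size=(8, 6)).astype(float),
            index=range(1, 9),
            columns=[f"M{i}" for i in range(6)],
        )
        cats.loc[7] = cats.loc[3]  # identical pair
        order, cm, om = phenotype.order_heatmap(cats, [f"M{i}" for i in range(4)])
        assert sorted(order) == list(range(1, 9))
        assert sorted(cm) == [f"M{i}" for i in range(4)]
        assert sorted(om) == ["M4", "M5"]
        assert abs(order.index(3) - order.index(7)) == 1

    def test_row_reversal_preserves_dendrogram_topology(self, rng):
        cats = pd.DataFrame(rng.integers(0, 5, size=(10, 5)).astype(float), index=range(1, 11))
        fwd = linkage(cats.to_numpy(), method="average", metric="euclidean")
        rev = linkage(cats.iloc[::-1].to_numpy(), method="average", metric="euclidean")
        # cophenetic distances between the same labelled pairs must agree
        cf_f = cophenet(fwd)
        cf_r = cophenet(rev)
        from scipy.spatial.distance import squareform

        Df = squareform(cf_f)
        Dr = squareform(cf_r)[::-1, ::-1]
        np.testing.assert_allclose(Df, Dr)


class TestAnnotate:
    def test_t_cell_rule(self):
        cats = pd.DataFrame(
            [[4, 0, 0, 0, 0, 0, 0, 0, 0]],
            index=[1],
            columns=["CD3", "CD11c", "CD14", "CD16", "CD19", "CD66", "CD123", "GranzymeB", "HLADR"],
        )
        ann = phenotype.annotate(cats, phenotype.default_rules())
        assert ann.loc[1] == "T-cell"

    def test_all_negative_is_unassigned(self):
        cats = pd.DataFrame(
            np.zeros((1, 9)),
            index=[1],
            columns=["CD3", "CD11c", "CD14", "CD16", "CD19", "CD66", "CD123", "GranzymeB", "HLADR"],
        )
        assert phenotype.annotate(cats, phenotype.default_rules()).loc[1] == "unassigned"

    def test_contradictory_rule_rejected(self):
        with pytest.raises(RuleError):
            phenotype.AnnotationRule("broken", [("CD3", ">=", 3), ("CD3", "<=", 1)])

    def test_priority_neutrophil_before_nk(self):
        # CD66 and CD16 both high: the neutrophil rule fires first
        cats = pd.DataFrame(
            [[0, 0, 0, 4, 0, 4, 0, 0, 0]],
            index=[1],
            columns=["CD3", "CD11c", "CD14", "CD16", "CD19", "CD66", "CD123", "GranzymeB", "HLADR"],
        )
        assert phenotype.annotate(cats, phenotype.default_rules()).loc[1] == "neutrophil"


class TestEndToEndRecovery:
    def test_cell_weighted_annotation_accuracy(self, small_cohort, small_tree, small_annotation):
        from cytoforge.synthetic import parent_label
        from cytoforge.workflows import POPULATION_DISPLAY

        _, annotation = small_annotation
        spec = small_cohort["spec"]
        truth = small_cohort["truth"]
        truth_parent = np.concatenate(
            [
                [POPULATION_DISPLAY[parent_label(l, spec)] for l in truth.labels[(s.sample_id, "unstimulated")]]
                for s in small_cohort["samples"]
            ]
        )
        predicted = annotation.reindex(small_tree.assignment).to_numpy(object)
        assert (predicted == truth_parent).mean() >= 0.95
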