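"""Subpopulation isolation, embedding, gating areas, area statistics, MSI."""

import numpy as np
import pandas as pd
import pytest

import cytoforge as cf
from cytoforge import subpop, synthetic
from cytoforge.errors import AreaError, DomainError, SelectionError

from conftest import make_matrix


class TestIsolate:
    def test_recovered_cells_are_mostly_true_neutrophils(
        self, small_cohort, small_tree, small_annotation
    ):
        _, annotation = small_annotation
        cells = subpop.isolate("neutrophil", small_tree, annotation, small_cohort["sampleset"])
        truth_all = np.concatenate(
            [small_cohort["truth"].labels[(s.sample_id, "unstimulated")] for s in small_cohort["samples"]]
        )
        mask = np.isin(small_tree.assignment, annotation.index[annotation == "neutrophil"])
        gt = truth_all[mask]
        frac = np.isin(gt, ["neutrophil", "neutrophil_cd11blow_cd16high"]).mean()
        assert cells.n_cells == mask.sum()
        assert frac >= 0.95

    def test_isolates_partition_the_cohort(self, small_cohort, small_tree, small_annotation):
        _, annotation = small_annotation
        total = sum(
            subpop.isolate(t, small_tree, annotation, small_cohort["sampleset"]).n_cells
            for t in annotation.unique()
        )
        assert total == len(small_tree.assignment)

    def test_absent_label_rejected(self, small_cohort, small_tree, small_annotation):
        _, annotation = small_annotation
        with pytest.raises(SelectionError):
            subpop.isolate("mast-cell", small_tree, annotation, small_cohort["sampleset"])


@pytest.fixture(scope="module")
def blob_embedding():
    rng = np.random.default_rng(3)
    a = rng.normal(0.0, 0.5, size=(300, 2))
    b = rng.normal(4.0, 0.5, size=(300, 2))  # 8-sigma separation
    m = cf.EventMatrix(
        values=np.vstack([a, b]), markers=["CD11b", "CD16"],
        transform="arcsinh", cofactor=5.0,
        provenance=np.array(["s1"] * 300 + ["s2"] * 300),
    )
    emb = subpop.embed(m, ["CD11b", "CD16"], n_per_sample=300, perplexity=30, iterations=1000, seed=5)
    return m, emb


class TestEmbed:
    def test_separation_preserved(self, blob_embedding):
        from sklearn.metrics import silhouette_score

        m, emb = blob_embedding
        labels = (emb.cells.values[:, 0] > 2.0).astype(int)  # ground truth via source blob
        assert silhouette_score(emb.coords, labels) > 0.5

    def test_equal_contribution_per_sample(self, blob_embedding):
        _, emb = blob_embedding
        counts = pd.Series(emb.sample_id).value_counts()
        assert counts.nunique() == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        m = cf.EventMatrix(
            values=rng.normal(2.0, 1.0, size=(200, 2)), markers=["A", "B"],
            transform="arcsinh", cofactor=5.0,
        )
        e1 = subpop.embed(m, ["A", "B"], n_per_sample=200, perplexity=10, iterations=260, seed=9)
        e2 = subpop.embed(m, ["A", "B"], n_per_sample=200, perplexity=10, iterations=260, seed=9)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_too_few_cells_rejected(self):
        m = make_matrix(np.random.default_rng(0).random((30, 2)), transform="arcsinh", cofactor=5.0)
        with pytest.raises(DomainError):
            subpop.embed(m, ["M0", "M1"], n_per_sample=30, perplexity=30, iterations=260, seed=0)


class TestAreas:
    def test_whole_plane_polygon_captures_everything(self):
        m = make_matrix(np.random.default_rng(1).random((50, 2)), transform="arcsinh", cofactor=5.0)
        coords = np.random.default_rng(2).uniform(-1, 1, size=(50, 2))
        emb = subpop.Embedding(coords=coords, cells=m, sample_id=np.array(["s"] * 50))
        big = subpop.AreaDefinition("all", "polygon", polygon=[(-10, -10), (10, -10), (10, 10), (-10, 10)])
        labels = subpop.assign_areas(emb, m, [big])
        assert (labels == "all").all()

    def test_boundary_point_counts_inside(self):
        m = make_matrix([[0.5, 0.5]], transform="arcsinh", cofactor=5.0)
        emb = subpop.Embedding(coords=np.array([[1.0, 0.0]]), cells=m, sample_id=np.array(["s"]))
        tri = subpop.AreaDefinition("t", "polygon", polygon=[(0, 0), (2, 0), (1, 2)])
        assert subpop.assign_areas(emb, m, [tri])[0] == "t"  # vertex-adjacent edge point
        emb2 = subpop.Embedding(coords=np.array([[2.0, 0.0]]), cells=m, sample_id=np.array(["s"]))
        assert subpop.assign_areas(emb2, m, [tri])[0] == "t"  # exactly on a vertex

    def test_overlapping_polygons_rejected_naming_pair(self):
        m = make_matrix([[0.0, 0.0]], transform="arcsinh", cofactor=5.0)
        emb = subpop.Embedding(coords=np.zeros((1, 2)), cells=m, sample_id=np.array(["s"]))
        a = subpop.AreaDefinition("left", "polygon", polygon=[(0, 0), (2, 0), (1, 2)])
        b = subpop.AreaDefinition("right", "polygon", polygon=[(1, 0), (3, 0), (2, 2)])
        with pytest.raises(AreaError, match="left.*right"):
            subpop.assign_areas(emb, m, [a, b])

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(AreaError, match="self-intersect"):
            subpop.AreaDefinition("bow", "polygon", polygon=[(0, 0), (2, 2), (2, 0), (0, 2)])

    def test_unmatched_cells_fall_into_rest(self):
        m = make_matrix([[0.0, 9.9], [9.9, 0.0]], markers=["CD11b", "CD16"], transform="arcsinh", cofactor=5.0)
        rule = subpop.AreaDefinition("gate", "marker_rule", rules=[("CD11b", "<=", 1.0), ("CD16", ">=", 5.0)])
        labels = subpop.assign_areas(None, m, [rule])
        assert labels.tolist() == ["gate", subpop.REST_AREA]

    def test_marker_rule_sensitivity_and_specificity(self):
        """The strict CD11b-low AND CD16-high gate finds the planted subpopulation."""
        rng = np.random.default_rng(11)
        n = 10_000
        spec = synthetic.default_cohort_spec(cells_per_sample=n, stimulated_pairs=False)
        patient = synthetic.simulate_clinical(9, fixture=True).iloc[8]  # longest duration
        events, labels, _ = synthetic.simulate_sample(spec, patient, seed=17)
        t = cf.arcsinh_transform(events, spec.cofactor)
        neut_mask = np.isin(labels, ["neutrophil", "neutrophil_cd11blow_cd16high"])
        neut = cf.EventMatrix(
            values=t.values[neut_mask], markers=t.markers, transform="arcsinh", cofactor=5.0
        )
        gt_sub = labels[neut_mask] == "neutrophil_cd11blow_cd16high"
        areas = subpop.default_neutrophil_areas(strict_cd16=True)
        got = subpop.assign_areas(None, neut, areas) == "Area 2"
        sensitivity = got[gt_sub].mean()
        specificity = (~got[~gt_sub]).mean()
        assert sensitivity >= 0.90 and specificity >= 0.90


class TestAreaPercentages:
    def test_single_area_everywhere(self):
        labels = np.array(["A"] * 40)
        sids = np.array(["r1"] * 10 + ["r2"] * 10 + ["h1"] * 10 + ["h2"] * 10)
        groups = {"r1": "RA", "r2": "RA", "h1": "healthy", "h2": "healthy"}
        stats = subpop.area_percentages(labels, sids, groups, mode="exact")
        assert (stats.per_sample["A"] == 100.0).all()
        assert stats.p_values["A"] == 1.0

    def test_per_sample_percentages_sum_to_100(self, rng):
        labels = rng.choice(["A", "B", "C"], size=200)
        sids = rng.choice(["r1", "r2", "h1", "h2"], size=200)
        groups = {"r1": "RA", "r2": "RA", "h1": "healthy", "h2": "healthy"}
        stats = subpop.area_percentages(labels, sids, groups, mode="exact")
        np.testing.assert_allclose(stats.per_sample.sum(axis=1), 100.0, atol=1e-9)

    def test_planted_group_difference_detected(self, rng):
        """30% vs 10% planted area occupancy at 7+5 samples: recovered and significant."""
        labels, sids = [], []
        for i in range(7):
            n = 2000
            is_area2 = rng.random(n) < 0.30
            labels.append(np.where(is_area2, "Area 2", "Area 1"))
            sids.append(np.full(n, f"r{i}"))
        for i in range(5):
            n = 2000
            is_area2 = rng.random(n) < 0.10
            labels.append(np.where(is_area2, "Area 2", "Area 1"))
            sids.append(np.full(n, f"h{i}"))
        groups = {f"r{i}": "RA" for i in range(7)} | {f"h{i}": "healthy" for i in range(5)}
        stats = subpop.area_percentages(np.concatenate(labels), np.concatenate(sids), groups, mode="exact")
        ra = stats.per_sample.loc[[f"r{i}" for i in range(7)], "Area 2"]
        hc = stats.per_sample.loc[[f"h{i}" for i in range(5)], "Area 2"]
        assert abs(ra.mean() - 30.0) < 3 and abs(hc.mean() - 10.0) < 3
        assert stats.p_values["Area 2"] < 0.05

    def test_empty_sample_warns(self):
        labels = np.array(["A", "A", "A", "A"])
        sids = np.array(["r1", "r1", "h1", "h1"])
        groups = {"r1": "RA", "h1": "healthy", "ghost": "RA"}
        with pytest.warns(UserWarning, match="ghost"):
            subpop.area_percentages(labels, sids, groups)


class TestCompareMsi:
    def test_identical_areas_equal_msi_and_p_one(self, rng):
        X = rng.normal(2.0, 0.3, size=(100, 1))
        m = cf.EventMatrix(
            values=np.vstack([X, X]), markers=["CD11b"], transform="arcsinh", cofactor=5.0,
            provenance=np.array(["s1"] * 50 + ["s2"] * 50 + ["s1"] * 50 + ["s2"] * 50),
        )
        labels = np.array(["A"] * 100 + ["B"] * 100)
        msi, pmat = subpop.compare_msi(m, labels, "CD11b", mode="exact")
        assert msi["A"] == pytest.approx(msi["B"])
        assert pmat.loc["A", "B"] == 1.0

    def test_constant_marker_msi_is_that_constant(self):
        m = cf.EventMatrix(
            values=np.full((60, 1), 2.5), markers=["CD16"], transform="arcsinh", cofactor=5.0,
            provenance=np.array(["s1"] * 30 + ["s2"] * 30),
        )
        labels = np.array(["A"] * 30 + ["B"] * 30)
        msi, _ = subpop.compare_msi(m, labels, "CD16")
        assert msi["A"] == 2.5 and msi["B"] == 2.5

    def test_planted_low_cd11b_detected(self, rng):
        """Area 2 carries the low CD11b mode: its MSI is lower with small p."""
        vals, labels, prov = [], [], []
        for i in range(5):
            hi = rng.normal(4.0, 0.4, size=300)
            lo = rng.normal(1.2, 0.4, size=100)
            vals.append(np.concatenate([hi, lo])[:, None])
            labels.append(np.array(["Area 1"] * 300 + ["Area 2"] * 100))
            prov.append(np.full(400, f"s{i}"))
        m = cf.EventMatrix(
            values=np.vstack(vals), markers=["CD11b"], transform="arcsinh", cofactor=5.0,
            provenance=np.concatenate(prov),
        )
        msi, pmat = subpop.compare_msi(m, np.concatenate(labels), "CD11b", mode="exact")
        assert msi["Area 2"] < msi["Area 1"]
        assert pmat.loc["Area 1", "Area 2"] < 0.05
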