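"""Synthetic cohort generator: clinical fixture, planted fractions, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from cytoforge import synthetic
from cytoforge.errors import SpecError
from cytoforge.panel import CYTOKINES, default_panel

TABLE_DURATIONS = [28, 172, 124, 76, 136, 76, 148, 244, 304]
TABLE_DAS28 = [2.70, 6.85, 5.49, 3.49, 2.68, 1.89, 2.58, 2.97, 2.56]


class TestClinical:
    def test_fixture_mode_returns_published_rows(self):
        clin = synthetic.simulate_clinical(9, seed=0, fixture=True)
        assert clin["duration_months"].tolist() == TABLE_DURATIONS
        assert clin["das28"].tolist() == pytest.approx(TABLE_DAS28)
        assert (clin["group"] == "RA").all()

    def test_sampled_durations_within_published_extrema(self):
        clin = synthetic.simulate_clinical(40, seed=3, fixture=False)
        assert clin["duration_months"].between(28, 304).all()
        assert clin["das28"].between(1.89, 6.85).all()

    def test_sampling_is_seeded(self):
        a = synthetic.simulate_clinical(12, seed=5, fixture=False)
        b = synthetic.simulate_clinical(12, seed=5, fixture=False)
        assert a.equals(b)


def _spec(**kw):
    return synthetic.default_cohort_spec(stimulated_pairs=False, **kw)


class TestSimulateSample:
    def test_degenerate_link_plants_nothing(self):
        spec = _spec(cells_per_sample=2000)
        spec.subpop_links[0].slope = 0.0
        spec.subpop_links[0].intercept = -50.0  # logit of ~0
        spec.subpop_links[0].noise_sd = 0.0
        patient = synthetic.simulate_clinical(9, fixture=True).iloc[0]
        _, labels, planted = synthetic.simulate_sample(spec, patient, seed=1)
        assert planted["neutrophil_cd11blow_cd16high"] == pytest.approx(0.0, abs=1e-12)
        assert (labels != "neutrophil_cd11blow_cd16high").all()

    def test_planted_fraction_concentrates(self):
        spec = _spec(cells_per_sample=10_000)
        link = spec.subpop_links[0]
        link.slope, link.noise_sd = 0.0, 0.0
        link.intercept = float(np.log(0.3 / 0.7))  # logit(0.3)
        patient = synthetic.simulate_clinical(9, fixture=True).iloc[0]
        _, labels, planted = synthetic.simulate_sample(spec, patient, seed=2)
        assert planted["neutrophil_cd11blow_cd16high"] == pytest.approx(0.3, abs=1e-12)
        n_sub = (labels == "neutrophil_cd11blow_cd16high").sum()
        n_par = (labels == "neutrophil").sum()
        assert abs(n_sub / (n_sub + n_par) - 0.3) < 0.02

    def test_unstimulated_cytokines_stay_at_baseline(self):
        spec = _spec(cells_per_sample=3000)
        patient = synthetic.simulate_clinical(9, fixture=True).iloc[0]
        events, _, _ = synthetic.simulate_sample(spec, patient, condition="unstimulated", seed=3)
        t = np.arcsinh(events.values / spec.cofactor)
        panel = default_panel()
        for cyt in CYTOKINES:
            col = t[:, panel.markers.index(cyt)]
            assert col.mean() < 0.5  # near the negative mode for every population

    def test_unknown_covariate_rejected(self):
        spec = _spec()
        with pytest.raises(SpecError):
            spec.subpop_links[0].covariate = "unknown"
            synthetic.CohortSpec(
                populations=spec.populations, subpop_links=spec.subpop_links
            )


class TestSimulateCohort:
    def test_default_shape_and_determinism(self):
        spec = _spec(cells_per_sample=300, seed=11)
        s1, clin, t1 = synthetic.simulate_cohort(spec)
        s2, _, t2 = synthetic.simulate_cohort(spec)
        assert (clin["group"] == "RA").sum() == 9
        assert (clin["group"] == "healthy").sum() == 5
        assert len(s1) == 14
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.values, b.values)
        assert t1.planted_fractions.equals(t2.planted_fractions)

    def test_labels_align_one_to_one_with_cells(self):
        spec = _spec(cells_per_sample=250, seed=4)
        samples, _, truth = synthetic.simulate_cohort(spec)
        pop_names = {p.name for p in spec.populations}
        for s in samples:
            labels = truth.labels[(s.sample_id, "unstimulated")]
            assert len(labels) == s.n_cells
            assert set(labels) <= pop_names

    def test_positive_duration_link_yields_positive_correlation(self):
        spec = synthetic.default_cohort_spec(
            n_ra=20, n_healthy=0, cells_per_sample=200, stimulated_pairs=False,
            clinical_fixture=False, seed=21,
        )
        _, clin, truth = synthetic.simulate_cohort(spec)
        planted = truth.planted_fractions["neutrophil_cd11blow_cd16high"]
        ra = clin[clin["group"] == "RA"]
        rho = sps.spearmanr(planted.loc[ra["patient_id"]], ra["duration_months"]).statistic
        assert rho > 0

    def test_fractions_converge_at_large_cell_count(self):
        spec = _spec(cells_per_sample=50_000, n_ra=1, n_healthy=1, seed=6)
        samples, _, truth = synthetic.simulate_cohort(spec)
        healthy = next(s for s in samples if s.group == "healthy")
        labels = truth.labels[(healthy.sample_id, "unstimulated")]
        base = {p.name: p.base_fraction for p in spec.populations}
        for link in spec.subpop_links:
            carved = link.healthy_fraction * base[link.parent]
            base[link.name] = carved
            base[link.parent] -= carved
        for name, expected in base.items():
            observed = (labels == name).mean()
            assert abs(observed - expected) < 0.01, name

    def test_zero_inflation_within_binomial_ci(self):
        spec = _spec(cells_per_sample=20_000, n_ra=1, n_healthy=0, seed=8)
        samples, _, truth = synthetic.simulate_cohort(spec)
        s = samples.samples[0]
        labels = truth.labels[(s.sample_id, "unstimulated")]
        t = np.arcsinh(s.values / spec.cofactor)
        panel = default_panel()
        # expressed mode (CD66 on neutrophils): truncation mass is negligible,
        # so exact zeros reflect the dropout probability alone
        neut = labels == "neutrophil"
        zi = synthetic.ZERO_INFLATION_POS
        zeros = (t[neut, panel.markers.index("CD66")] == 0.0).mean()
        n = int(neut.sum())
        half = 2.576 * np.sqrt(zi * (1 - zi) / n)
        assert abs(zeros - zi) < half
        # negative mode (CD19 on neutrophils): truncation of the Gaussian at
        # zero adds non-detections on top of dropout, so zeros >= dropout
        zeros_neg = (t[neut, panel.markers.index("CD19")] == 0.0).mean()
        assert zeros_neg >= synthetic.ZERO_INFLATION_NEG
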