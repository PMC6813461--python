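"""Shared fixtures: a small synthetic cohort and its SPADE tree.

The session-scoped cohort (9 RA + 5 healthy, 1500 cells/sample, k = 40) is
computed once and reused by the phenotype / differential-abundance /
subpopulation tests; acceptance tests build their own cohorts at the study
scale.
"""

import numpy as np
import pytest

import cytoforge as cf
from cytoforge import phenotype, spade, synthetic

COHORT_SEED = 20240915


@pytest.fixture(scope="session")
def panel():
    return cf.default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    spec = synthetic.default_cohort_spec(
        cells_per_sample=1500, stimulated_pairs=False, seed=COHORT_SEED
    )
    samples, clin, truth = synthetic.simulate_cohort(spec, panel=panel)
    transformed = [cf.arcsinh_transform(s, spec.cofactor) for s in samples]
    return {
        "spec": spec,
        "samples": samples,
        "transformed": transformed,
        "sampleset": cf.SampleSet(samples=transformed, panel=panel),
        "clinical": clin,
        "truth": truth,
        "groups": dict(zip(clin["patient_id"], clin["group"])),
    }


@pytest.fixture(scope="session")
def small_tree(small_cohort, panel):
    return spade.run_spade(
        small_cohort["transformed"],
        markers=panel.subset("all33"),
        k=40,
        target_fraction=0.1,
        seed=COHORT_SEED,
    )


@pytest.fixture(scope="session")
def small_annotation(small_cohort, small_tree):
    pooled = cf.concatenate(small_cohort["transformed"])
    ranges = phenotype.marker_ranges(pooled)
    categories = phenotype.categorize(small_tree, ranges)
    return categories, phenotype.annotate(categories, phenotype.default_rules())


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_matrix(values, markers=None, **kw):
    values = np.asarray(values, dtype=float)
    markers = markers or [f"M{i}" for i in range(values.shape[1])]
    return cf.EventMatrix(values=values, markers=markers, **kw)
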