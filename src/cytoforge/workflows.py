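"""High-level validation workflows over the synthetic cohort.

These functions run the full analysis chain against the generator's planted
ground truth and return the headline numbers: how accurately clusters are
annotated to their true populations, how well the CD11b(low) CD16(high)
gate recovers the planted within-neutrophil fractions, whether at least one
corresponding cluster is flagged RA-enriched, the clinical correlations,
and the stimulation-arm detection/null behaviour.  They are used by the
repository's analysis drivers and acceptance checks; problem sizes default
to the desk-scale study shape (9 RA + 5 healthy, 10k cells/sample, k = 100).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clinical as clin_mod
from . import phenotype, spade, stimulation, subpop, synthetic
from .diffabund import cluster_enrichment
from .io import SampleSet, arcsinh_transform, concatenate
from .synthetic import parent_label

POPULATION_DISPLAY = {
    "neutrophil": "neutrophil",
    "t_cell": "T-cell",
    "b_cell": "B-cell",
    "nk": "NK",
    "monocyte": "monocyte",
    "cdc": "cDC",
    "pdc": "pDC",
    "basophil": "basophil",
}

NEUTROPHIL_SUBPOP = "neutrophil_cd11blow_cd16high"
TCELL_SUBPOP = "t_cd11ahigh_gzmbhigh"


def _transformed(samples: SampleSet, cofactor: float) -> list:
    return [arcsinh_transform(s, cofactor) for s in samples]


def end_to_end_recovery(
    seed: int,
    cells_per_sample: int = 10_000,
    k: int = 100,
    downsample_fraction: float = 0.05,
) -> dict:
    """Full unstimulated-arm pipeline on the default synthetic cohort.

    Returns a dict with: ``annotation_accuracy_pct`` (cell-weighted % of
    cells lying in clusters annotated with their true population),
    ``recovery_max_abs_error_points`` / ``recovery_mean_abs_error_points``
    (per-sample |gate estimate - planted fraction| of the within-neutrophil
    subpopulation, in percentage points), ``min_ra_enriched_p`` (smallest
    exact permutation p among RA-enriched neutrophil clusters),
    ``duration_rho`` / ``duration_p`` (Spearman of the gate estimate vs
    disease duration), pooled area occupancies, and problem-size metadata.
    """
    spec = synthetic.default_cohort_spec(
        cells_per_sample=cells_per_sample, stimulated_pairs=False, seed=int(seed)
    )
    samples, clin, truth = synthetic.simulate_cohort(spec)
    tr = _transformed(samples, spec.cofactor)
    panel = samples.panel
    tree = spade.run_spade(
        tr, markers=panel.subset("all33"), k=k, target_fraction=downsample_fraction, seed=int(seed)
    )
    pooled = concatenate(tr)
    ranges = phenotype.marker_ranges(pooled)
    categories = phenotype.categorize(tree, ranges)
    annotation = phenotype.annotate(categories, phenotype.default_rules())

    # cell-weighted annotation accuracy against ground truth
    truth_parent = np.concatenate(
        [
            [POPULATION_DISPLAY[parent_label(l, spec)] for l in truth.labels[(s.sample_id, "unstimulated")]]
            for s in samples
        ]
    )
    predicted = annotation.reindex(tree.assignment).to_numpy(object)
    accuracy_pct = 100.0 * float((predicted == truth_parent).mean())

    # differential abundance: RA-enriched neutrophil clusters
    abundance = spade.abundance_table(tree.assignment, tree.cell_sample, tree.k)
    groups = dict(zip(clin["patient_id"], clin["group"]))
    enrich = cluster_enrichment(abundance, groups, mode="exact", seed=int(seed))
    neut_clusters = annotation.index[annotation == "neutrophil"]
    ra_neut = enrich.loc[
        enrich.index.intersection(neut_clusters)
    ].query("trend == 'RA-enriched'")
    min_p = float(ra_neut["p_value"].min()) if len(ra_neut) else float("nan")

    # subpopulation gate recovery
    ss = SampleSet(samples=tr, panel=panel)
    neut = subpop.isolate("neutrophil", tree, annotation, ss)
    labels = subpop.assign_areas(None, neut, subpop.default_neutrophil_areas())
    stats = subpop.area_percentages(labels, neut.provenance, groups, mode="exact", seed=int(seed))
    est = stats.per_sample["Area 2"]
    # ground truth = the within-neutrophil fraction actually realized in each
    # sample's emitted cells (the link parameter in truth.planted_fractions
    # carries additional multinomial noise no estimator could remove)
    realized = {}
    for sid in est.index:
        lab = truth.labels[(sid, "unstimulated")]
        n_sub = int((lab == NEUTROPHIL_SUBPOP).sum())
        n_par = int((lab == "neutrophil").sum())
        realized[sid] = 100.0 * n_sub / (n_sub + n_par)
    err = (est - pd.Series(realized)).abs()
    corr = clin_mod.correlate_abundance(est, clin, "duration_months")

    return {
        "annotation_accuracy_pct": accuracy_pct,
        "recovery_max_abs_error_points": float(err.max()),
        "recovery_mean_abs_error_points": float(err.mean()),
        "min_ra_enriched_p": min_p,
        "n_ra_enriched_neutrophil_clusters": int(len(ra_neut)),
        "area2_p": float(stats.p_values["Area 2"]),
        "duration_rho": float(corr.rho),
        "duration_p": float(corr.p_two_sided),
        "pooled_area2_pct_ra": float(stats.pooled.loc["RA", "Area 2"]),
        "pooled_area2_pct_healthy": float(stats.pooled.loc["healthy", "Area 2"]),
        "pooled_area1_pct_ra": float(stats.pooled.loc["RA", "Area 1"]),
        "pooled_area1_pct_healthy": float(stats.pooled.loc["healthy", "Area 1"]),
        "n_cells": int(pooled.n_cells),
        "k": int(k),
    }


def stimulation_detection(
    seed: int,
    cells_per_sample: int = 3000,
    k: int = 100,
    responder_fraction: float = 0.3,
    downsample_fraction: float = 0.05,
) -> dict:
    """Full stimulation-arm pipeline: re-cluster stimulated/control pairs at
    k clusters on the 20-marker set, score cytokine positivity, and test
    stimulated-vs-control and RA-vs-healthy per (population, cytokine).
    """
    spec = synthetic.default_cohort_spec(
        cells_per_sample=cells_per_sample,
        stimulated_pairs=True,
        responder_fraction=responder_fraction,
        seed=int(seed),
    )
    samples, clin, _ = synthetic.simulate_cohort(spec)
    tr = _transformed(samples, spec.cofactor)
    panel = samples.panel
    tree = spade.run_spade(
        tr, markers=panel.subset("stim20"), k=k, target_fraction=downsample_fraction, seed=int(seed)
    )
    pooled = concatenate(tr)
    categories = phenotype.categorize(tree, phenotype.marker_ranges(pooled))
    annotation = phenotype.annotate(categories, phenotype.stimulation_rules())
    cell_pop = annotation.reindex(tree.assignment).to_numpy(object)
    cell_condition = np.concatenate([np.full(s.n_cells, s.condition, dtype=object) for s in tr])
    table = stimulation.response_table(
        tr, cell_pop, tree.cell_sample, cell_condition, populations=["monocyte", "cDC", "pDC"]
    )
    groups = dict(zip(clin["patient_id"], clin["group"]))
    # stim-vs-control pools 2x14 samples: auto mode falls back to Monte Carlo
    # there while the 9-vs-5 group comparison stays exact
    comparison = stimulation.compare_response(table, groups, mode="auto", seed=int(seed))
    mono = comparison.query("population == 'monocyte'").set_index("cytokine")
    return {
        "comparison": comparison,
        "monocyte_tnfa_p_stim": float(mono.loc["TNF-a", "p_stim_vs_control"]),
        "monocyte_tnfa_p_group": float(mono.loc["TNF-a", "p_ra_vs_healthy"]),
        "monocyte_tnfa_pct_stimulated": float(mono.loc["TNF-a", "mean_pct_stimulated"]),
        "monocyte_tnfa_pct_control": float(mono.loc["TNF-a", "mean_pct_control"]),
        "n_cells": int(pooled.n_cells),
        "k": int(k),
    }


def stimulation_null_calibration(
    seed: int, n_reps: int = 100, cells_per_sample: int = 400, alpha: float = 0.05
) -> dict:
    """RA-vs-healthy rejection rate when responder fractions are equal.

    Per repetition a small paired cohort is simulated (equal responder
    fraction in both groups by construction), monocyte cytokine positivity
    is scored against each cohort's own controls using the *ground-truth*
    monocyte labels (no clustering — this isolates the test's calibration
    from clustering noise), and the exact RA-vs-healthy permutation test is
    applied to the stimulated percentages.
    """
    rejections = 0
    pvals = []
    for rep in range(n_reps):
        spec = synthetic.default_cohort_spec(
            cells_per_sample=cells_per_sample,
            stimulated_pairs=True,
            clinical_fixture=False,
            seed=(int(seed) * 1009 + rep) & 0x7FFFFFFF,
        )
        samples, clin, truth = synthetic.simulate_cohort(spec)
        tr = _transformed(samples, spec.cofactor)
        cell_pop = np.concatenate(
            [
                [parent_label(l, spec) for l in truth.labels[(s.sample_id, s.condition)]]
                for s in tr
            ]
        )
        cell_sample = np.concatenate([np.full(s.n_cells, s.sample_id, dtype=object) for s in tr])
        cell_condition = np.concatenate([np.full(s.n_cells, s.condition, dtype=object) for s in tr])
        table = stimulation.response_table(
            tr, cell_pop, cell_sample, cell_condition, populations=["monocyte"], cytokines=["TNF-a"]
        )
        groups = dict(zip(clin["patient_id"], clin["group"]))
        stim = table[table["condition"] == "TLR_stimulated"].set_index("sample")["percent_positive"]
        ra = stim[[groups[s] == "RA" for s in stim.index]].dropna()
        hc = stim[[groups[s] == "healthy" for s in stim.index]].dropna()
        from .diffabund import permutation_test

        p = permutation_test(ra.to_numpy(), hc.to_numpy(), mode="exact")
        pvals.append(p)
        if p < alpha:
            rejections += 1
    return {
        "rejection_rate": rejections / n_reps,
        "n_reps": n_reps,
        "p_values": np.asarray(pvals),
    }
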