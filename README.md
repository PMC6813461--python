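# cytoforge

Mass-cytometry (CyTOF) cohort analysis for immunophenotyping studies of
rheumatoid arthritis (RA): SPADE-style clustering, categorical phenotype
heatmaps, permutation-based differential cluster abundance, viSNE-area
subpopulation quantification, Spearman clinical correlation, and
TLR-stimulation cytokine-response scoring — together with a synthetic
multi-sample cohort generator that plants disease-linked subpopulations
with known ground truth, so every stage of the pipeline can be validated
end to end.

The package is aimed at cytometrists and computational immunologists who
want the analysis chain behind "RA-enriched leukocyte subpopulation"
findings as tested, scriptable code: whole-blood leukocytes from 9 RA
patients and 5 healthy donors measured on a 33-marker panel, clustered
jointly, annotated to cell types, and mined for subpopulations such as
CD11b^low CD16^high neutrophils (rising with disease duration) and
CD11a^high Granzyme B^high T-cells (inversely related to DAS28).

## Methods at a glance

* **Transform** — arcsinh, `y = asinh(x / c)` with cofactor `c = 5`, the
  CyTOF convention.
* **SPADE** — per-cell local density (L1 neighbourhood counts),
  density-dependent downsampling to a target fraction (5%) via
  `P(keep_i) = min(1, TD / density_i)` with TD solved by bisection,
  average-linkage L1 agglomeration cut at *k* clusters (k = 500 at full
  scale, 100 for the stimulation arm and desk-scale runs), a minimum
  spanning tree over cluster medians, and nearest-median upsampling of all
  cells.
* **Categorical phenotyping** — per marker, the pooled 5th–95th percentile
  range is split into five equal bins (negative/low/medium/high/bright);
  each cluster's mean-over-samples of per-sample medians is binned, and
  clusters are annotated to cell types by ordered threshold rules over the
  categories (e.g. neutrophil: CD66 ≥ 3).
* **Differential abundance** — per cluster, abundance = fraction of a
  sample's cells; trend = sign of mean(RA) − mean(healthy); significance
  from the exact permutation distribution of |mean(RA) − mean(healthy)|
  over all C(14, 5) = 2002 group relabelings.
* **Subpopulations** — cells of an annotated population are isolated,
  embedded with Barnes–Hut t-SNE (equal cells per sample), and partitioned
  into explicit areas (polygons in embedding space or marker-rule gates on
  the arcsinh scale); per-sample area percentages and per-area marker MSI
  (mean signal intensity) are compared by permutation with samples as the
  unit.
* **Clinical correlation** — Spearman's ρ on mid-ranks; for n ≤ 10 without
  ties the two-sided p comes from exact enumeration of the rank-statistic
  null (all n! orders of S = Σd²), otherwise from the Student-t
  approximation `t = ρ√((n−2)/(1−ρ²))` — matching R's `cor.test`.
* **Stimulation response** — percentage of cells above a control-referenced
  positivity threshold (99th percentile of the matched population in the
  PBS control) for MIP-1β, TNF-α and IL-8.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (shared run directory `results/run`, 2500 cells/sample, k = 60):

```sh
cd analysis
python 01_simulate_cohort.py
python 02_spade_clustering.py
python 03_phenotype_heatmap.py
python 04_differential_abundance.py
python 05_neutrophil_subpopulation.py
python 06_clinical_correlations.py
python 07_tlr_stimulation.py
python 08_report.py
```

`05_neutrophil_subpopulation.py` prints, for the default seed:

```
pooled neutrophil area occupancy (%):
group
RA         66.0    34.0
healthy    88.8    11.2
RA vs healthy permutation p per area:
Area 1   0.0015
Area 2   0.0015
```

i.e. 34.0% of RA neutrophils versus 11.2% of healthy neutrophils fall in
the CD11b^low gate (Area 2), and the per-sample percentages differ
significantly between groups under the exact permutation test.
`06_clinical_correlations.py` then reports the Area-2 percentage against
disease duration:

```
neutrophil Area 2  duration_months  rho=0.954  p=0.0001  (t_approximation)
```

— a strong positive duration correlation (the t-approximation is used
because the published durations contain a tie at 76 months).
`07_tlr_stimulation.py` shows cytokine induction after TLR stimulation
(≈1% positive monocytes in controls versus ≈40% stimulated, p = 1e-4)
with no RA-vs-healthy difference, as planted.

The same chain is available behind one command: `cytoforge run --out DIR
--seed 1`, configured by a YAML file (see `cytoforge.pipeline.PipelineConfig`).

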