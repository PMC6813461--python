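# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the cytoforge pipeline and its synthetic cohort generator.

## Data model and transform

A sample is a cells × markers matrix of nonnegative ion counts with a
sample id, stimulation condition (unstimulated / TLR-stimulated) and
clinical group (RA / healthy). All analysis operates on the
variance-stabilized scale `y = asinh(x / c)`. The cofactor defaults to
`c = 5`, the mass-cytometry convention; it is a configuration key because
fluorescence data wants larger values. Inputs are assumed bead-normalized
upstream; the pipeline neither implements nor requires bead normalization.

FCS 3.0/3.1 list-mode files are read and written natively (float, double
and 16/32-bit unsigned integer DATA segments, both byte orders; channel
names from `$PnS` falling back to `$PnN`). Writing always emits
little-endian float32 without timestamps, so rewriting re-read data is
byte-identical. A CSV fallback (header row of marker names, one cell per
line) supports text-only pipelines; CSV reads use round-trip float
parsing, so write→read is exact.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, not raw
instrument physics. Per sample:

* **Populations.** Cell labels are drawn multinomially from baseline blood
  fractions (neutrophils 55%, T 25%, monocytes 8%, B 5%, NK 5%, cDC 1.2%,
  pDC 0.4%, basophils 0.4%). Each population has a marker signature on the
  arcsinh scale with modes negative = 0.15, low = 1.2, medium = 2.5,
  high = 4.0, very high = 5.5 and SD 0.4, built from the nine annotation
  markers plus canonical immunology (e.g. neutrophils CD66/CD16/CD11b
  high; monocytes CD14/HLADR high; pDC CD123/HLADR high).
* **Planted subpopulations.** Two links carve subpopulations out of their
  parents on the logit scale. The CD11b^low CD16^very-high neutrophil
  subpopulation has within-neutrophil fraction
  `sigmoid(a + b·duration + ε)` for RA patients with `b = 0.006/month` and
  `a` set so the fraction averages ≈ 0.337 over the observed duration
  range (≈ 0.18 at 28 months to ≈ 0.54 at 304 months), `ε ~ N(0, 0.2)`;
  healthy donors sit at 0.092. The CD11a^very-high Granzyme-B^very-high
  T-cell subpopulation is present per RA patient with probability 5/9
  (mirroring the bimodal group-A/group-B split) and, when present, shrinks
  with DAS28 (`slope −0.5`); healthy baseline 0.033. The per-patient link
  noise and presence draw are condition-independent, so stimulated /
  control mates share their ground truth.
* **Noise.** Gaussian on the arcsinh scale (not ion-count Poisson — the
  pipeline only ever sees transformed data), zero-inflated per marker
  (dropout 0.30 at negative modes, 0.02 at expressed modes), truncated at
  zero, plus one per-sample batch shift `N(0, 0.05)` applied to every
  marker. Dropout zeros are re-imposed after the batch shift: a
  non-detection stays an exact zero. Note that truncation itself creates
  additional exact zeros at negative modes (≈ 35% of a N(0.15, 0.4) draw
  is below zero), which is physically sensible; the dropout probability is
  therefore only directly observable at expressed modes.
* **Stimulation.** Under TLR stimulation a responder fraction (default
  0.4) of monocytes/cDC/pDC shifts its MIP-1β/TNF-α/IL-8 modes upward by
  4 SD; all other populations never produce cytokines.
* **Clinical covariates.** With 9 RA patients the verbatim published
  characteristics table is used (fixture mode) — notably its tied disease
  durations (76 months twice), which force the Spearman t-approximation
  exactly as in the original analysis environment. Otherwise durations are
  uniform over [28, 304] months, DAS28 uniform over [1.89, 6.85], and
  treatment/serology flags follow the published empirical frequencies.

Emitted samples are raw counts (`sinh(y)·c`), so the pipeline's own
transform reproduces the latent values exactly. What the generator does
*not* emulate: bead events, doublets, acquisition drift, isotope spillover,
heavy-tailed instrument noise, or correlated marker noise within a cell.
Passing tests therefore demonstrate correctness of the analysis chain
under the stated statistical structure, not robustness to every instrument
artifact of real data.

## SPADE clustering

Density: the local density of cell *i* is the number of cells within L1
distance `α·d_med` of it over the clustering markers, where `d_med` is the
median nearest-neighbour distance in a seeded subsample of 2000 cells and
`α = 5`. For inputs larger than the reference size the neighbour count is
computed against the same reference subsample and rescaled to the full
cell count — a near-linear approximation that leaves small-fixture
behaviour exact. Densities are floored at 1 (every cell sees itself).

Downsampling: each cell is retained with probability `min(1, TD/density)`;
the target density TD is found by bisection so the expected retained
fraction is within 0.2 percentage points of the target (5% by default).
Retention is Bernoulli, so the realized fraction carries binomial noise on
top. An optional 1st-percentile density floor (outlier removal) exists but
is off by default.

Clustering: average-linkage agglomeration with the L1 metric, cut at *k*
clusters. The joint cohort (all samples, and both conditions in the
stimulation arm) is clustered together. The MST over pooled cluster
medians uses L1 edge weights. Upsampling assigns every original cell to
the nearest pooled median, ties broken toward the lower cluster id
(within a 1e-9 absolute tolerance to absorb float noise). Empty clusters
keep their ids with zero abundance rather than being renumbered.

k defaults: 500 for a full-scale primary run; desk-scale validation and
the stimulation arm use k = 100, and the bundled analysis drivers k = 60 —
chosen as the package's own working sizes for a 14-sample synthetic
cohort.

## Categorical phenotyping and annotation

Marker ranges are the 5th and 95th percentiles (linear-interpolation
definition) over **all pooled cells**; the alternative of computing ranges
over cluster medians is a configuration switch (`marker_ranges` accepts
any matrix) since either convention appears in published heatmaps.
For cluster *c* and marker *m*, the value binned is the mean over samples
of the per-(cluster, sample) medians — samples contributing no cells to
the cluster are excluded from the mean; clusters empty everywhere get a
missing (NaN) category row. The [p5, p95] interval splits into five
equal-width, left-closed bins with the last bin closed; values outside
clamp to categories 0 and 4. A degenerate range (p5 = p95) maps equal
values to the middle category. Categorization is monotone by construction.

Annotation applies ordered threshold rules over categories: neutrophil
CD66 ≥ 3; T-cell CD3 ≥ 3 ∧ CD66 ≤ 1; B-cell CD19 ≥ 3; pDC CD123 ≥ 3 ∧
HLADR ≥ 3; basophil CD123 ≥ 3 ∧ HLADR ≤ 1; monocyte CD14 ≥ 3; NK CD16 ≥ 3
∧ CD3 ≤ 1 ∧ CD66 ≤ 1; cDC CD11c ≥ 3 ∧ HLADR ≥ 3 ∧ CD14 ≤ 1 — first match
wins, no match is "unassigned". Priority resolves genuine marker overlap
(neutrophils are CD16-positive; monocytes express CD11c/HLADR). The
stimulation arm annotates on the CD64-bearing marker set; the thresholds
above gate only on surface lineage markers, so the same rule set applies.

## Differential abundance

The statistic is the absolute difference of group means of per-sample
abundance fractions. The exact permutation distribution is enumerated when
the number of distinct relabelings C(n, n_RA) is ≤ 10^6 (the study design
gives 2002); otherwise Monte-Carlo relabeling with the add-one correction
`p = (1 + #{stat ≥ obs}) / (1 + n_perm)`. Ties with the observed statistic
count toward the numerator (within a small relative tolerance), so the
test is exact-level and p > 0 always. No multiple-testing correction by
default; Benjamini–Hochberg is available behind a flag. With unequal group
sizes the permutation distribution is asymmetric — e.g. for (0,0,0,0) vs
(10,11,12,13,14) only the identity relabeling attains the observed
statistic, giving p = 1/126.

## Subpopulation areas and MSI

Because the original areas were drawn by eye on viSNE maps, this package
requires explicit area definitions: polygons in embedding space (simple
polygons; boundary counts as inside; overlapping polygons are rejected
naming the pair) or conjunctive marker rules on the arcsinh scale. Cells
matching nothing fall into "rest".

The default neutrophil Area-2 gate is **CD11b ≤ 2.6** — the midpoint
between the normal-neutrophil high mode (4.0) and the subpopulation low
mode (1.2). CD11b is the marker that defines the subpopulation; its CD16
expression is heterogeneous, and requiring CD16 above its midpoint
(4.75, only 1.9 SD below the subpopulation mode) would lose the ~2% of
subpopulation cells whose CD16 reads as a detection zero plus a ~3–5%
Gaussian tail — a miss rate that scales with the planted fraction and
biases per-sample recovery by up to ~3.5 points at the longest-duration
patient. The CD11b-only gate separates the modes by 7 SD and is immune to
dropout (a zero still reads "low"), holding the per-sample recovery error
under ~2 points; the conjunctive CD11b^low ∧ CD16^high variant remains
available (`strict_cd16=True`) and still achieves ≥ 90% sensitivity and
specificity. The T-cell Area-1 gate is CD11a ≥ 4.0 ∧ Granzyme B ≥ 2.825
(midpoints between the bulk-T and subpopulation modes).

t-SNE uses the Barnes–Hut implementation (perplexity 30, 1000 iterations,
PCA initialization, fixed seed) on an equal per-sample subsample of
min(smallest sample, 5000) cells; the bundled drivers embed 300
cells/sample to keep the demonstration fast. Area percentages are reported
both per sample (each row summing to 100) and pooled per group, since a
group-level percentage can be computed either way. MSI is the mean
arcsinh-scale intensity over an area's cells; both area-percentage and MSI
comparisons permute per-sample values, never per-cell values, to avoid
pseudo-replication.

Recovery is scored against the subpopulation fraction *realized* in each
sample's emitted cells rather than the logit-link parameter, which
additionally carries multinomial sampling noise that no estimator could
remove; both quantities are exposed.

## Spearman correlation

ρ is the Pearson correlation of mid-ranks. With no ties and n ≤ 10 the
two-sided p is exact: the null distribution of S = Σ(rank difference)² is
enumerated over all n! rank orders (cached per n) and
`p = min(1, 2·min(P(S ≤ s), P(S ≥ s)))`. With ties, or n > 10, p comes
from `t = ρ√((n−2)/(1−ρ²))` against Student's t with n−2 df. This
reproduces the behaviour of R's `cor.test`, including which method the
data force: the published duration column is tied, so duration
correlations use the t-approximation, while the untied DAS28 column at
n = 9 uses exact enumeration. Healthy donors carry NA clinical fields and
are excluded from correlations automatically. |ρ| = 1 under the
t-approximation is clamped to the smallest positive float rather than
reported as 0.

## Stimulation response

Positivity thresholds are control-referenced: the 99th percentile of the
cytokine's arcsinh intensity among the matched population's cells in the
same sample's PBS control, falling back to the pooled control cells of
that population when the per-sample population has fewer than 100 cells
(relevant for pDC at small cell yields). A control scored against itself
therefore sits near 1% positive by construction. Percent-positive is the
percentage strictly above threshold, making it invariant under any
monotone transform applied to cells and threshold alike. The stimulation
arm re-clusters all profiles at k = 100 on the 20-marker surface set
rather than reusing the primary tree. Stimulated-vs-control and
RA-vs-healthy comparisons permute per-sample percentages (the
stimulated-vs-control pool of 28 values exceeds the exact limit and falls
back to Monte Carlo; the 9-vs-5 group comparison stays exact).

## Pipeline

Stages (simulate → cluster → phenotype → diffabund → subpop → correlate →
stimulate → report) read and write versioned directories under one run
directory, log ISO-8601-stamped events with the SHA-256 configuration
hash, and are bit-reproducible for all non-figure outputs. A single global
seed expands to per-stage seeds as `seed·100 + stage_index`, so stages can
be rerun in isolation.

## Problem sizes

Full-scale validation runs the study shape — 9 RA + 5 healthy,
10 000 cells/sample (140k cells), k = 100, 5% downsampling — in under a
minute on one CPU; the stimulation validation uses 3000 cells/sample over
28 paired profiles. The analysis drivers use 2500 cells/sample and k = 60
as a compact demonstration. k = 500 at higher cell counts is supported but
not exercised by the bundled runs.

## Known limitations

* Density estimation above the reference size is an approximation (exact
  counting is quadratic); rare-population densities are noisier than in
  exhaustive SPADE.
* The permutation test treats stimulated/control pairs as independent
  groups (conservative for paired designs).
* Annotation rules encode one canonical marker logic; real panels with
  different clones/epitopes need their own rule file.
* The generator's Gaussian, per-marker-independent noise understates the
  correlated heterogeneity of real leukocyte populations, so recovery
  accuracies here are upper bounds for real data.
* Exact Spearman enumeration is limited to n ≤ 10 (the n = 10 null is
  3.6M permutations, cached after first use).
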