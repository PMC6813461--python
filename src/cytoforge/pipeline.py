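"""Pipeline orchestration: staged, seeded, reproducible runs.

Stages (canonical order): ``simulate`` -> ``cluster`` -> ``phenotype`` ->
``diffabund`` -> ``subpop`` -> ``correlate`` -> ``stimulate`` -> ``report``.
Each stage reads the previous stages' on-disk outputs under the run
directory, writes its own subdirectory, and appends one ISO-8601-stamped
line per event to ``run.log`` including the configuration hash.  Rerunning
with an identical configuration reproduces all non-figure outputs
bit-identically.

A single global seed is expanded into per-stage seeds as
``base_seed * 100 + stage_index`` (stage indices follow the canonical
order), so any stage can be rerun in isolation with the same randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin_mod
from . import phenotype, spade, stimulation, subpop, synthetic
from .diffabund import cluster_enrichment, summarize
from .errors import DependencyError, DomainError
from .io import SampleSet, arcsinh_transform, read_sample, write_sample
from .panel import default_panel

STAGES = ["simulate", "cluster", "phenotype", "diffabund", "subpop", "correlate", "stimulate", "report"]


@dataclass
class PipelineConfig:
    """All tunables of a run; every field has a working default."""

    seed: int = 0
    cofactor: float = 5.0
    sample_format: str = "csv"  # csv | fcs
    # simulate
    n_ra: int = 9
    n_healthy: int = 5
    cells_per_sample: int = 10_000
    stimulated_pairs: bool = True
    clinical_fixture: bool = True
    # cluster
    k_main: int = 100
    k_stim: int = 100
    downsample: float = 0.05
    cluster_markers: str = "all33"
    density_alpha: float = 5.0
    # diffabund
    alpha: float = 0.05
    permutation_mode: str = "auto"
    n_perm: int = 10_000
    # subpop / embedding
    embed: bool = False
    embed_cells_per_sample: int = 200
    tsne_perplexity: float = 30.0
    tsne_iterations: int = 500

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 100 + STAGES.index(stage)) & 0x7FFFFFFF


class _Run:
    def __init__(self, config: PipelineConfig, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.panel = default_panel()

    def log(self, message: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(self.out / "run.log", "a") as fh:
            fh.write(f"{stamp} config={self.config.hash()} {message}\n")

    def stage_dir(self, stage: str, must_exist: bool = False) -> Path:
        d = self.out / stage
        if must_exist and not d.is_dir():
            raise DependencyError(f"stage {stage!r} has not run yet; run it first")
        return d

    # -- stage implementations -------------------------------------------

    def simulate(self) -> None:
        cfg = self.config
        spec = synthetic.default_cohort_spec(
            n_ra=cfg.n_ra,
            n_healthy=cfg.n_healthy,
            cells_per_sample=cfg.cells_per_sample,
            stimulated_pairs=cfg.stimulated_pairs,
            clinical_fixture=cfg.clinical_fixture,
            cofactor=cfg.cofactor,
            seed=cfg.stage_seed("simulate"),
        )
        samples, clin, truth = synthetic.simulate_cohort(spec, panel=self.panel)
        d = self.stage_dir("simulate")
        (d / "cohort").mkdir(parents=True, exist_ok=True)
        (d / "ground_truth").mkdir(exist_ok=True)
        ext = cfg.sample_format
        for s in samples:
            tag = f"{s.sample_id}__{s.condition}"
            write_sample(s, d / "cohort" / f"{tag}.{ext}", format=ext)
            pd.Series(
                truth.labels[(s.sample_id, s.condition)], name="population"
            ).to_csv(d / "ground_truth" / f"{tag}.labels.tsv", sep="\t", index_label="cell")
        clin.to_csv(d / "clinical.csv", index=False)
        clin_mod.to_published(clin).to_csv(d / "clinical_published.csv", index=False)
        truth.planted_fractions.to_csv(d / "planted_fractions.csv", index_label="sample")
        self.log(f"simulate: wrote {len(samples)} samples to {d / 'cohort'}")

    def _load_clinical(self) -> pd.DataFrame:
        d = self.stage_dir("simulate", must_exist=True)
        clin = pd.read_csv(d / "clinical.csv", dtype={"treatments": str}, keep_default_na=False)
        clin["das28"] = pd.to_numeric(clin["das28"], errors="coerce")
        clin["duration_months"] = pd.to_numeric(clin["duration_months"], errors="coerce")
        return clin

    def _load_cohort(self, condition: str | None = "unstimulated") -> tuple[SampleSet, pd.DataFrame]:
        d = self.stage_dir("simulate", must_exist=True)
        clin = self._load_clinical()
        group_of = dict(zip(clin["patient_id"], clin["group"]))
        samples = []
        for path in sorted((d / "cohort").iterdir()):
            stem = path.stem
            sid, cond = stem.split("__", 1)
            if condition is not None and cond != condition:
                continue
            m = read_sample(path, panel=self.panel, sample_id=sid, condition=cond, group=group_of[sid])
            samples.append(arcsinh_transform(m, self.config.cofactor))
        return SampleSet(samples=samples, panel=self.panel), clin

    def cluster(self) -> None:
        cfg = self.config
        samples, _ = self._load_cohort("unstimulated")
        tree = spade.run_spade(
            samples,
            markers=self.panel.subset(cfg.cluster_markers),
            k=cfg.k_main,
            target_fraction=cfg.downsample,
            alpha=cfg.density_alpha,
            seed=cfg.stage_seed("cluster"),
        )
        d = self.stage_dir("cluster")
        spade.save_tree(tree, d / "tree")
        abundance = spade.abundance_table(tree.assignment, tree.cell_sample, tree.k)
        abundance.to_csv(d / "abundance.csv", index_label="cluster")
        self.log(f"cluster: k={cfg.k_main}, {len(tree.assignment)} cells, {len(tree.empty_clusters)} empty clusters")

    def phenotype(self) -> None:
        samples, _ = self._load_cohort("unstimulated")
        tree = spade.load_tree(self.stage_dir("cluster", must_exist=True) / "tree")
        from .io import concatenate

        pooled = concatenate(list(samples))
        ranges = phenotype.marker_ranges(pooled)
        categories = phenotype.categorize(tree, ranges)
        annotation = phenotype.annotate(categories, phenotype.default_rules())
        d = self.stage_dir("phenotype")
        d.mkdir(exist_ok=True)
        ranges.to_csv(d / "ranges.csv", index_label="marker")
        categories.to_csv(d / "categories.csv", index_label="cluster")
        annotation.to_csv(d / "annotation.csv")
        cluster_order, cm, om = phenotype.order_heatmap(categories, tree.markers)
        (d / "orders.json").write_text(
            json.dumps({"clusters": [int(c) for c in cluster_order], "clustering_markers": cm, "other_markers": om})
        )
        phenotype.render_heatmap(categories, d / "heatmap.png", tree.markers, annotation)
        self.log(f"phenotype: {annotation.value_counts().to_dict()}")

    def diffabund(self) -> None:
        cfg = self.config
        clin = self._load_clinical()
        abundance = pd.read_csv(self.stage_dir("cluster", must_exist=True) / "abundance.csv", index_col="cluster")
        annotation = pd.read_csv(
            self.stage_dir("phenotype", must_exist=True) / "annotation.csv", index_col="cluster"
        )["annotation"]
        groups = dict(zip(clin["patient_id"], clin["group"]))
        enrich = cluster_enrichment(
            abundance, groups, mode=cfg.permutation_mode, n_perm=cfg.n_perm,
            alpha=cfg.alpha, seed=cfg.stage_seed("diffabund"),
        )
        enrich["annotation"] = annotation.reindex(enrich.index)
        summary = summarize(enrich["trend"], annotation.reindex(enrich.index).fillna("unassigned"))
        d = self.stage_dir("diffabund")
        d.mkdir(exist_ok=True)
        enrich.to_csv(d / "enrichment.csv", index_label="cluster")
        summary.to_csv(d / "summary.csv", index_label="cell_type")
        self.log(
            f"diffabund: {(enrich['trend'] == 'RA-enriched').mean():.3f} RA-enriched, "
            f"{int(enrich['significant'].sum())} significant at alpha={cfg.alpha}"
        )

    def _subpop_arm(self, celltype: str, defs, out_name: str, d: Path) -> pd.DataFrame:
        cfg = self.config
        samples, clin = self._load_cohort("unstimulated")
        tree = spade.load_tree(self.stage_dir("cluster", must_exist=True) / "tree")
        annotation = pd.read_csv(
            self.stage_dir("phenotype", must_exist=True) / "annotation.csv", index_col="cluster"
        )["annotation"]
        cells = subpop.isolate(celltype, tree, annotation, samples)
        labels = subpop.assign_areas(None, cells, defs)
        groups = dict(zip(clin["patient_id"], clin["group"]))
        stats = subpop.area_percentages(
            labels, cells.provenance, groups, mode=cfg.permutation_mode, seed=cfg.stage_seed("subpop")
        )
        stats.per_sample.to_csv(d / f"{out_name}_per_sample_pct.csv", index_label="sample")
        stats.pooled.to_csv(d / f"{out_name}_pooled_pct.csv", index_label="group")
        stats.p_values.to_csv(d / f"{out_name}_area_p.csv", index_label="area")
        if cfg.embed:
            markers = subpop.DEFAULT_EMBED_MARKERS[celltype]
            emb = subpop.embed(
                cells, markers, n_per_sample=cfg.embed_cells_per_sample,
                perplexity=cfg.tsne_perplexity, iterations=cfg.tsne_iterations,
                seed=cfg.stage_seed("subpop"),
            )
            emb.to_frame().to_csv(d / f"{out_name}_embedding.tsv", sep="\t", index_label="cell")
        return stats.per_sample

    def subpop(self) -> None:
        d = self.stage_dir("subpop")
        d.mkdir(exist_ok=True)
        per_sample = self._subpop_arm("neutrophil", subpop.default_neutrophil_areas(), "neutrophil", d)
        cells_t = None
        try:
            self._subpop_arm("T-cell", subpop.default_tcell_areas(), "tcell", d)
            cells_t = True
        except Exception as exc:  # T-cell arm is best-effort on tiny cohorts
            self.log(f"subpop: T-cell arm skipped ({exc})")
        self.log(f"subpop: neutrophil areas over {len(per_sample)} samples; tcell_arm={bool(cells_t)}")

    def correlate(self) -> None:
        d = self.stage_dir("correlate")
        d.mkdir(exist_ok=True)
        clin = self._load_clinical()
        sp = self.stage_dir("subpop", must_exist=True)
        rows = []
        for arm, area, covs in [
            ("neutrophil", "Area 2", ["duration_months", "das28"]),
            ("tcell", "Area 1", ["das28", "duration_months"]),
        ]:
            path = sp / f"{arm}_per_sample_pct.csv"
            if not path.exists():
                continue
            pct = pd.read_csv(path, index_col="sample")
            if area not in pct.columns:
                continue
            series = pct[area]
            for cov in covs:
                try:
                    res = clin_mod.correlate_abundance(series, clin, cov)
                except Exception as exc:
                    self.log(f"correlate: {arm}/{cov} failed ({exc})")
                    continue
                rows.append(
                    {
                        "arm": arm, "area": area, "covariate": cov, "rho": res.rho,
                        "p_two_sided": res.p_two_sided, "method": res.method,
                        "n": res.n, "ties_present": res.ties_present,
                    }
                )
        pd.DataFrame(rows).to_csv(d / "correlations.csv", index=False)
        self.log(f"correlate: {len(rows)} correlations computed")

    def stimulate(self) -> None:
        cfg = self.config
        samples, clin = self._load_cohort(None)
        if not any(s.condition == "TLR_stimulated" for s in samples):
            raise DependencyError("no stimulated samples in the cohort; simulate with stimulated_pairs")
        sample_list = list(samples)
        tree = spade.run_spade(
            sample_list,
            markers=self.panel.subset("stim20"),
            k=cfg.k_stim,
            target_fraction=cfg.downsample,
            alpha=cfg.density_alpha,
            seed=cfg.stage_seed("stimulate"),
        )
        from .io import concatenate

        pooled = concatenate(sample_list)
        ranges = phenotype.marker_ranges(pooled)
        categories = phenotype.categorize(tree, ranges)
        annotation = phenotype.annotate(categories, phenotype.stimulation_rules())
        cell_pop = annotation.reindex(tree.assignment).to_numpy(object)
        cell_condition = np.concatenate([np.full(s.n_cells, s.condition, dtype=object) for s in sample_list])
        table = stimulation.response_table(
            sample_list, cell_pop, tree.cell_sample, cell_condition,
            populations=["monocyte", "cDC", "pDC"],
        )
        groups = dict(zip(clin["patient_id"], clin["group"]))
        comparison = stimulation.compare_response(table, groups, mode=cfg.permutation_mode, seed=cfg.stage_seed("stimulate"))
        d = self.stage_dir("stimulate")
        d.mkdir(exist_ok=True)
        table.to_csv(d / "percent_positive.csv", index=False)
        comparison.to_csv(d / "comparison.csv", index=False)
        self.log(f"stimulate: k={cfg.k_stim}; {len(table)} percent-positive rows")

    def report(self) -> None:
        d = self.stage_dir("report")
        d.mkdir(exist_ok=True)
        lines = [f"cytoforge run report (config {self.config.hash()})", ""]
        summary = self.stage_dir("diffabund", must_exist=True) / "summary.csv"
        lines += ["== cluster enrichment summary ==", (summary.read_text()), ""]
        corr = self.out / "correlate" / "correlations.csv"
        if corr.exists():
            lines += ["== clinical correlations ==", corr.read_text(), ""]
        comp = self.out / "stimulate" / "comparison.csv"
        if comp.exists():
            lines += ["== stimulation comparisons ==", comp.read_text(), ""]
        (d / "summary.txt").write_text("\n".join(lines))
        self.log("report: written")


def run(config: PipelineConfig, stages: list[str], out_dir) -> Path:
    """Execute the requested stages in canonical order; returns the run directory."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise DomainError(f"unknown stages: {unknown}")
    runner = _Run(config, out_dir)
    config.to_yaml(runner.out / "config.yaml")
    for stage in STAGES:
        if stage in stages:
            t0 = time.perf_counter()
            getattr(runner, stage)()
            runner.log(f"{stage}: done in {time.perf_counter() - t0:.1f}s seed={config.stage_seed(stage)}")
    return runner.out
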