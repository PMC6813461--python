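"""Shared configuration for the numbered analysis drivers.

All drivers operate on one run directory (``results/run``) with a desk-scale
configuration: the study's cohort shape (9 RA + 5 healthy, paired
stimulated/control samples) at 2500 cells per sample and 60 clusters, which
keeps every step under a minute while preserving the cohort structure the
full-scale validation (scripts/acceptance.py) exercises at 10k cells and
k = 100.
"""

from pathlib import Path

from cytoforge.pipeline import PipelineConfig

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(
        seed=seed,
        cells_per_sample=2500,
        k_main=60,
        k_stim=60,
        stimulated_pairs=True,
        embed=True,
        embed_cells_per_sample=300,
        tsne_iterations=500,
    )
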