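"""Simulate the synthetic study cohort.

Generates 9 RA + 5 healthy whole-blood samples (paired TLR-stimulated /
PBS-control), the clinical table, and the planted ground truth, and writes
them under results/run/simulate/.
"""

import pandas as pd

from common import RUN_DIR, config
from cytoforge.pipeline import run


def main() -> None:
    cfg = config()
    run(cfg, ["simulate"], RUN_DIR)
    clin = pd.read_csv(RUN_DIR / "simulate" / "clinical.csv")
    planted = pd.read_csv(RUN_DIR / "simulate" / "planted_fractions.csv", index_col=0)
    print(f"wrote {2 * len(clin)} samples ({(clin.group == 'RA').sum()} RA, "
          f"{(clin.group == 'healthy').sum()} healthy) x {cfg.cells_per_sample} cells")
    print("planted within-neutrophil subpopulation fractions (RA rises with duration):")
    print((100 * planted["neutrophil_cd11blow_cd16high"]).round(1).to_string())


if __name__ == "__main__":
    main()
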