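"""Neutrophil subpopulation quantification.

Isolates all cells in neutrophil-annotated clusters, partitions them into
the CD11b(low) gate (Area 2) versus the rest (Area 1), embeds an equal
per-sample subsample with Barnes-Hut t-SNE on CD11b/CD16, and reports
per-sample and pooled area percentages with RA-vs-healthy permutation
p-values.  The T-cell arm (CD11a/Granzyme-B Area 1) runs alongside.
"""

import pandas as pd

from common import RUN_DIR, config
from cytoforge.pipeline import run


def main() -> None:
    run(config(), ["subpop"], RUN_DIR)
    pooled = pd.read_csv(RUN_DIR / "subpop" / "neutrophil_pooled_pct.csv", index_col="group")
    pvals = pd.read_csv(RUN_DIR / "subpop" / "neutrophil_area_p.csv", index_col="area")
    print("pooled neutrophil area occupancy (%):")
    print(pooled.round(1).to_string())
    print("RA vs healthy permutation p per area:")
    print(pvals.round(4).to_string())


if __name__ == "__main__":
    main()
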