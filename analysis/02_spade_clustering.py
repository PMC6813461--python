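"""SPADE clustering of the unstimulated cohort.

Density-dependent downsampling to 5%, average-linkage L1 agglomeration into
k clusters, MST over cluster medians, upsampling of all cells; writes the
tree and the clusters x samples abundance table under results/run/cluster/.
"""

import pandas as pd

from common import RUN_DIR, config
from cytoforge.pipeline import run


def main() -> None:
    cfg = config()
    run(cfg, ["cluster"], RUN_DIR)
    abundance = pd.read_csv(RUN_DIR / "cluster" / "abundance.csv", index_col="cluster")
    print(f"clustered into k={cfg.k_main}; abundance table {abundance.shape[0]} clusters "
          f"x {abundance.shape[1]} samples (columns sum to {abundance.sum().iloc[0]:.3f})")
    top = abundance.mean(axis=1).sort_values(ascending=False).head(5)
    print("largest clusters (mean fraction of a sample):")
    print(top.round(3).to_string())


if __name__ == "__main__":
    main()
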