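"""Differential cluster abundance: RA vs healthy enrichment trends and
exact permutation p-values per cluster, plus the per-cell-type summary."""

import pandas as pd

from common import RUN_DIR, config
from cytoforge.pipeline import run


def main() -> None:
    run(config(), ["diffabund"], RUN_DIR)
    enrich = pd.read_csv(RUN_DIR / "diffabund" / "enrichment.csv", index_col="cluster")
    summary = pd.read_csv(RUN_DIR / "diffabund" / "summary.csv", index_col="cell_type")
    n_sig = int(enrich["significant"].sum())
    print(f"{(enrich.trend == 'RA-enriched').mean():.1%} of clusters trend RA-enriched; "
          f"{n_sig} significant at alpha=0.05 (exact permutation)")
    print("per cell type (fraction of clusters, fraction of those RA-enriched):")
    print(summary.round(3).to_string())


if __name__ == "__main__":
    main()
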