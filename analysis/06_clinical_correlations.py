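"""Clinical correlation of subpopulation sizes.

Spearman correlation of the per-patient Area-2 neutrophil percentage with
disease duration (t-approximation: the published durations carry a tie)
and of the T-cell Area-1 percentage with DAS28 (exact enumeration at n=9
when untied)."""

import pandas as pd

from common import RUN_DIR, config
from cytoforge.pipeline import run


def main() -> None:
    run(config(), ["correlate"], RUN_DIR)
    corr = pd.read_csv(RUN_DIR / "correlate" / "correlations.csv")
    print(corr.round(4).to_string(index=False))
    neut = corr.query("arm == 'neutrophil' and covariate == 'duration_months'")
    if len(neut):
        row = neut.iloc[0]
        print(f"\nneutrophil Area-2 %% vs disease duration: rho={row.rho:.3f}, "
              f"p={row.p_two_sided:.4f} ({row.method})")


if __name__ == "__main__":
    main()
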