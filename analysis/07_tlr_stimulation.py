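"""TLR-stimulation arm.

Re-clusters all stimulated/control profiles at k clusters on the 20-marker
surface set, annotates monocytes/cDC/pDC, scores the percentage of cells
positive for MIP-1b, TNF-a and IL-8 against control-referenced thresholds,
and tests stimulated-vs-control and RA-vs-healthy differences."""

import pandas as pd

from common import RUN_DIR, config
from cytoforge.pipeline import run


def main() -> None:
    run(config(), ["stimulate"], RUN_DIR)
    comp = pd.read_csv(RUN_DIR / "stimulate" / "comparison.csv")
    print(comp.round(4).to_string(index=False))
    detected = comp["p_stim_vs_control"] < 0.05
    print(f"\ncytokine induction detected in {int(detected.sum())}/{len(comp)} "
          "(population, cytokine) combinations; RA vs healthy differences: "
          f"{int((comp['p_ra_vs_healthy'] < 0.05).sum())} significant")


if __name__ == "__main__":
    main()
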