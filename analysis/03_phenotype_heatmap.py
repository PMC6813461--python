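"""Categorical phenotyping and cell-type annotation of the SPADE clusters.

Computes pooled 5th-95th percentile marker ranges, bins each cluster's
mean-of-medians expression into five categories, renders the categorical
heatmap, and annotates clusters to cell types by the default marker rules.
"""

import pandas as pd

from common import RUN_DIR, config
from cytoforge.pipeline import run


def main() -> None:
    run(config(), ["phenotype"], RUN_DIR)
    ann = pd.read_csv(RUN_DIR / "phenotype" / "annotation.csv", index_col="cluster")["annotation"]
    print("cluster annotation counts:")
    print(ann.value_counts().to_string())
    print(f"heatmap written to {RUN_DIR / 'phenotype' / 'heatmap.png'}")


if __name__ == "__main__":
    main()
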