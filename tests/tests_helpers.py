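"""Small helpers shared across test modules."""

import numpy as np
import pandas as pd

from cytoforge.spade import SpadeTree


def tree_from_mean_medians(mean_medians: pd.DataFrame) -> SpadeTree:
    """A minimal SpadeTree whose mean-of-medians equals the given table
    (single pseudo-sample, one cell per cluster)."""
    med = mean_medians.copy()
    med.index = pd.MultiIndex.from_product([med.index, ["s1"]], names=["cluster", "sample"])
    return SpadeTree(
        k=int(mean_medians.index.max()),
        assignment=np.asarray(mean_medians.index),
        cell_sample=np.array(["s1"] * len(mean_medians)),
        medians=med,
        pooled_medians=mean_medians,
        pooled_medians_all=mean_medians,
        mst_edges=[],
        markers=list(mean_medians.columns),
        sample_order=["s1"],
    )
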