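"""Categorical phenotyping of clusters and rule-based cell-type annotation.

Each cluster x marker combination is summarized by the mean over samples of
the per-(cluster, sample) expression medians, then discretized into five
categories — negative (0), low (1), medium (2), high (3), bright (4) — by
splitting the pooled 5th-95th percentile range of that marker into five
equal-width bins.  Bins are left-closed/right-open with the last bin
closed; values outside the range clamp to the extreme categories.  The
resulting clusters x markers category matrix is the "categorical heatmap";
hierarchical clustering (average linkage, Euclidean) orders its rows and,
separately, the clustering-marker and remaining-marker columns.

Cell types are then assigned by an ordered rule list over the category
matrix (e.g. neutrophil: CD66 >= 3).  The default rules encode the
annotation markers used in the study (CD3, CD11c, CD14, CD16, CD19, CD66,
CD123, Granzyme B, HLADR) with canonical immunology:

========== =============================================
neutrophil CD66 >= 3
T-cell     CD3 >= 3 and CD66 <= 1
B-cell     CD19 >= 3
pDC        CD123 >= 3 and HLADR >= 3
basophil   CD123 >= 3 and HLADR <= 1
monocyte   CD14 >= 3
NK         CD16 >= 3 and CD3 <= 1 and CD66 <= 1
cDC        CD11c >= 3 and HLADR >= 3 and CD14 <= 1
========== =============================================

The first matching rule wins; clusters matching nothing are "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import InputError, RuleError
from .io import EventMatrix
from .spade import SpadeTree

N_CATEGORIES = 5
CELL_TYPES = ["T-cell", "B-cell", "neutrophil", "NK", "monocyte", "cDC", "pDC", "basophil", "unassigned"]


def marker_ranges(all_cells: EventMatrix, lo: float = 5.0, hi: float = 95.0) -> pd.DataFrame:
    """Per-marker (p5, p95) over all pooled cells, linear-interpolation quantiles."""
    p = np.percentile(all_cells.values, [lo, hi], axis=0)
    return pd.DataFrame({"p5": p[0], "p95": p[1]}, index=all_cells.markers)


def mean_of_medians(tree: SpadeTree) -> pd.DataFrame:
    """Cluster x marker mean over samples of the per-(cluster, sample) medians.

    Samples contributing zero cells to a cluster simply have no median row
    and are excluded from the mean; clusters empty in every sample yield a
    row of NaN.
    """
    v = tree.medians.groupby(level="cluster").mean()
    return v.reindex(range(1, tree.k + 1))


def categorize(tree: SpadeTree, ranges: pd.DataFrame) -> pd.DataFrame:
    """Five-level categories per (cluster, marker); NaN rows flag clusters
    empty in all samples."""
    v = mean_of_medians(tree)
    missing_markers = [m for m in v.columns if m not in ranges.index]
    if missing_markers:
        raise InputError(f"ranges missing markers: {missing_markers}")
    p5 = ranges.loc[v.columns, "p5"].to_numpy()
    p95 = ranges.loc[v.columns, "p95"].to_numpy()
    width = p95 - p5
    vals = v.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.floor(N_CATEGORIES * (vals - p5) / width)
    # degenerate range (p5 == p95): below -> 0, above -> 4, equal -> middle
    deg = width == 0
    if deg.any():
        d = np.broadcast_to(deg, vals.shape)
        idx = np.where(d, np.where(vals < p5, 0, np.where(vals > p95, 4, 2)), idx)
    idx = np.clip(idx, 0, N_CATEGORIES - 1)
    idx[np.isnan(vals)] = np.nan
    out = pd.DataFrame(idx, index=v.index, columns=v.columns)
    return out


def order_heatmap(
    categories: pd.DataFrame, clustering_markers: list[str]
) -> tuple[list, list[str], list[str]]:
    """Leaf orders from hierarchical clustering (average linkage, Euclidean)
    of category vectors: clusters, clustering-marker columns, other columns."""
    cats = categories.dropna(how="any")

    def _order(frame: pd.DataFrame) -> list:
        if len(frame) <= 1:
            return list(frame.index)
        Z = linkage(frame.to_numpy(), method="average", metric="euclidean")
        return [frame.index[i] for i in leaves_list(Z)]

    cluster_order = _order(cats)
    cmark = [m for m in categories.columns if m in clustering_markers]
    omark = [m for m in categories.columns if m not in clustering_markers]
    return cluster_order, _order(cats[cmark].T), _order(cats[omark].T) if omark else []


@dataclass
class AnnotationRule:
    """Cell-type rule: all (marker, comparator, category-threshold) must hold."""

    cell_type: str
    requirements: list[tuple[str, str, int]]  # (marker, ">=" or "<=", threshold)

    def __post_init__(self) -> None:
        bounds: dict[str, list[float]] = {}
        for marker, cmp, thr in self.requirements:
            if cmp not in (">=", "<="):
                raise RuleError(f"{self.cell_type}: comparator must be >= or <=, got {cmp!r}")
            lo_hi = bounds.setdefault(marker, [-np.inf, np.inf])
            if cmp == ">=":
                lo_hi[0] = max(lo_hi[0], thr)
            else:
                lo_hi[1] = min(lo_hi[1], thr)
            if lo_hi[0] > lo_hi[1]:
                raise RuleError(
                    f"{self.cell_type}: contradictory bounds on {marker} ({lo_hi[0]} > {lo_hi[1]})"
                )

    def matches(self, row: pd.Series) -> bool:
        for marker, cmp, thr in self.requirements:
            if marker not in row.index:
                raise RuleError(f"{self.cell_type}: unknown marker {marker!r}")
            v = row[marker]
            if pd.isna(v):
                return False
            if cmp == ">=" and not v >= thr:
                return False
            if cmp == "<=" and not v <= thr:
                return False
        return True


def default_rules() -> list[AnnotationRule]:
    """Default annotation rule set (priority order as listed)."""
    return [
        AnnotationRule("neutrophil", [("CD66", ">=", 3)]),
        AnnotationRule("T-cell", [("CD3", ">=", 3), ("CD66", "<=", 1)]),
        AnnotationRule("B-cell", [("CD19", ">=", 3)]),
        AnnotationRule("pDC", [("CD123", ">=", 3), ("HLADR", ">=", 3)]),
        AnnotationRule("basophil", [("CD123", ">=", 3), ("HLADR", "<=", 1)]),
        AnnotationRule("monocyte", [("CD14", ">=", 3)]),
        AnnotationRule("NK", [("CD16", ">=", 3), ("CD3", "<=", 1), ("CD66", "<=", 1)]),
        AnnotationRule("cDC", [("CD11c", ">=", 3), ("HLADR", ">=", 3), ("CD14", "<=", 1)]),
    ]


def stimulation_rules() -> list[AnnotationRule]:
    """Rule set for the stimulation arm.

    The stimulation arm annotates on CD64 instead of Granzyme B; since the
    default rules gate only on surface lineage markers the thresholds are
    identical — kept as a separate entry point so arm-specific rules stay
    configurable.
    """
    return default_rules()


def annotate(categories: pd.DataFrame, rules: list[AnnotationRule]) -> pd.Series:
    """First-matching-rule cell type per cluster; no match -> 'unassigned'."""
    labels = {}
    for cluster, row in categories.iterrows():
        label = "unassigned"
        for rule in rules:
            if rule.matches(row):
                label = rule.cell_type
                break
        labels[cluster] = label
    return pd.Series(labels, name="annotation").rename_axis("cluster")


def render_heatmap(
    categories: pd.DataFrame,
    path,
    clustering_markers: list[str] | None = None,
    annotation: pd.Series | None = None,
) -> None:
    """Render the categorical heatmap (white -> dark red, five levels) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, LinearSegmentedColormap

    clustering_markers = clustering_markers or list(categories.columns)
    cluster_order, cm_order, om_order = order_heatmap(categories, clustering_markers)
    cols = cm_order + om_order
    data = categories.loc[cluster_order, cols].to_numpy(dtype=float)
    cmap = LinearSegmentedColormap.from_list("cat", ["#ffffff", "#fcbba1", "#fb6a4a", "#cb181d", "#67000d"], N=5)
    norm = BoundaryNorm(np.arange(-0.5, 5.5), 5)
    height = max(3.0, 0.04 * len(cluster_order) + 1.5)
    fig, ax = plt.subplots(figsize=(0.28 * len(cols) + 2, height))
    im = ax.imshow(data, aspect="auto", cmap=cmap, norm=norm, interpolation="nearest")
    ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(cluster_order)} clusters")
    cbar = fig.colorbar(im, ax=ax, ticks=range(5))
    cbar.ax.set_yticklabels(["negative", "low", "medium", "high", "bright"])
    if annotation is not None:
        counts = annotation.loc[cluster_order].value_counts()
        ax.set_title(", ".join(f"{t}: {c}" for t, c in counts.items()), fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
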