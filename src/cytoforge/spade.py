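"""SPADE-style clustering: density-dependent downsampling, agglomerative
clustering, MST over cluster medians, and upsampling of all cells.

The algorithm follows the classic spanning-tree progression analysis of
density-normalized events:

1. estimate each cell's local density (neighbours within a radius set by the
   median nearest-neighbour distance of a seeded subsample, scaled by a
   kernel multiplier ``alpha``, L1 metric over the clustering markers);
2. downsample density-dependently so dense regions are thinned and rare
   populations survive, targeting a retained fraction (the study setting is
   5%);
3. cluster the retained cells agglomeratively (average linkage, L1) cut at
   ``k`` clusters (500 for the main arm, 100 for the stimulation arm);
4. build a minimum spanning tree over the pooled cluster medians (L1); and
5. upsample: assign every original cell to the nearest cluster median.

Densities and medians are computed over the concatenation of all samples
(the cohort is clustered jointly); per-(cluster, sample) medians over all
panel markers feed the categorical phenotyping downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import DomainError, InputError
from .io import EventMatrix, SampleSet, concatenate

_CHUNK = 20_000


@dataclass
class DensityEstimate:
    """Per-cell local density (each cell counts itself, so density >= 1)."""

    density: np.ndarray
    kernel_alpha: float
    radius: float
    distance_metric: str = "L1"
    n_cells: int = 0

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        self.n_cells = self.density.size
        if (self.density < 1).any():
            raise DomainError("densities must be >= 1")


@dataclass
class SpadeTree:
    """Cluster assignment plus medians and MST for one SPADE run."""

    k: int
    assignment: np.ndarray  # per-cell cluster id in 1..k (concatenated cell order)
    cell_sample: np.ndarray  # per-cell source sample_id
    medians: pd.DataFrame  # MultiIndex (cluster, sample) x all markers
    pooled_medians: pd.DataFrame  # cluster x clustering markers (assignment space)
    pooled_medians_all: pd.DataFrame  # cluster x all markers
    mst_edges: list[tuple[int, int, float]]
    markers: list[str]  # clustering markers
    sample_order: list[str] = field(default_factory=list)

    @property
    def empty_clusters(self) -> list[int]:
        present = set(np.unique(self.assignment))
        return [c for c in range(1, self.k + 1) if c not in present]


def _l1_count_within(X: np.ndarray, ref: np.ndarray, radius: float) -> np.ndarray:
    """For each row of X, the number of rows of ref within L1 distance <= radius."""
    out = np.empty(X.shape[0], dtype=np.int64)
    for start in range(0, X.shape[0], _CHUNK):
        block = X[start : start + _CHUNK]
        d = cdist(block, ref, metric="cityblock")
        out[start : start + _CHUNK] = (d <= radius + 1e-12).sum(axis=1)
    return out


def estimate_density(
    m: EventMatrix,
    markers: list[str],
    alpha: float = 5.0,
    seed: int = 0,
    ref_size: int = 2000,
) -> DensityEstimate:
    """Local density: neighbours within ``alpha * d_med`` (L1), where d_med is
    the median nearest-neighbour distance of a seeded subsample of up to 2000
    cells.

    The neighbour count is exact when the sample holds at most *ref_size*
    cells; above that it is estimated against the same seeded reference
    subsample and rescaled to the full cell count (documented numerical
    choice — keeps the step near-linear at cohort scale).
    """
    if alpha <= 0:
        raise DomainError("alpha must be positive")
    if not markers:
        raise DomainError("clustering marker set is empty")
    X = m.values[:, m.marker_index(markers)]
    n = X.shape[0]
    if n < 2:
        raise DomainError("density estimation needs at least 2 cells")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    sub_idx = rng.choice(n, size=min(ref_size, n), replace=False)
    sub = X[sub_idx]
    d_sub = squareform(pdist(sub, metric="cityblock"))
    np.fill_diagonal(d_sub, np.inf)
    nn = d_sub.min(axis=1)
    d_med = float(np.median(nn[np.isfinite(nn)])) if np.isfinite(nn).any() else 0.0
    radius = alpha * d_med
    if n <= ref_size:
        counts = _l1_count_within(X, X, radius).astype(np.float64)
    else:
        counts = _l1_count_within(X, sub, radius).astype(np.float64) * (n / sub.shape[0])
    density = np.maximum(counts, 1.0)
    return DensityEstimate(density=density, kernel_alpha=alpha, radius=radius)


def downsample(
    m: EventMatrix,
    d: DensityEstimate,
    target_fraction: float,
    seed: int = 0,
    tol: float = 0.002,
) -> tuple[EventMatrix, np.ndarray]:
    """Density-dependent downsampling to an expected retained fraction.

    Each cell is kept with probability ``min(1, TD / density)``; the target
    density TD is found by bisection so the expected retained fraction is
    within *tol* (0.2 percentage points) of *target_fraction*.  Returns the
    retained cells and their indices into *m*.
    """
    if not (0.0 < target_fraction <= 1.0):
        raise DomainError(f"target_fraction must be in (0, 1], got {target_fraction}")
    if d.n_cells != m.n_cells:
        raise InputError("density estimate is not aligned with the sample")
    dens = d.density
    n = dens.size
    if target_fraction >= 1.0:
        keep = np.ones(n, dtype=bool)
    else:
        lo, hi = 0.0, float(dens.max())

        def expected(td: float) -> float:
            return float(np.minimum(1.0, td / dens).mean())

        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if expected(mid) < target_fraction:
                lo = mid
            else:
                hi = mid
            if abs(expected(0.5 * (lo + hi)) - target_fraction) <= tol:
                break
        td = 0.5 * (lo + hi)
        prob = np.minimum(1.0, td / dens)
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        keep = rng.random(n) < prob
        if not keep.any():  # degenerate tiny inputs: keep the sparsest cell
            keep[int(np.argmin(dens))] = True
    idx = np.flatnonzero(keep)
    sub = EventMatrix(
        values=m.values[idx],
        markers=list(m.markers),
        sample_id=m.sample_id,
        condition=m.condition,
        group=m.group,
        transform=m.transform,
        cofactor=m.cofactor,
        provenance=None if m.provenance is None else m.provenance[idx],
    )
    return sub, idx


def cluster(
    sub: EventMatrix, markers: list[str], k: int, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Agglomerative clustering (average linkage, L1) cut at k clusters.

    Returns ``(medians, assignment)``: per-cluster pooled medians over the
    clustering markers (index = cluster ids 1..k) and per-cell cluster ids.
    The *seed* parameter is accepted for interface uniformity; the
    agglomeration itself is deterministic.
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    if sub.n_cells < k:
        raise DomainError(f"cannot form {k} clusters from {sub.n_cells} cells")
    X = sub.values[:, sub.marker_index(markers)]
    Z = linkage(X, method="average", metric="cityblock")
    assignment = fcluster(Z, t=k, criterion="maxclust")
    # maxclust can return fewer clusters when ties collapse; relabel to 1..k' contiguously
    ids = np.unique(assignment)
    relabel = {old: new for new, old in enumerate(ids, start=1)}
    assignment = np.array([relabel[a] for a in assignment], dtype=np.int64)
    medians = (
        pd.DataFrame(X, columns=markers)
        .groupby(assignment)
        .median()
        .rename_axis("cluster")
    )
    return medians, assignment


def build_mst(medians: pd.DataFrame) -> list[tuple[int, int, float]]:
    """Minimum spanning tree over cluster medians (L1); k-1 edges."""
    if medians.index.duplicated().any():
        raise DomainError("duplicate cluster ids in medians")
    if len(medians) < 2:
        raise DomainError("MST needs at least 2 clusters")
    ids = list(medians.index)
    D = squareform(pdist(medians.to_numpy(), metric="cityblock"))
    mst = minimum_spanning_tree(D).tocoo()
    edges = [(ids[i], ids[j], float(w)) for i, j, w in zip(mst.row, mst.col, mst.data)]
    edges.sort()
    return edges


def upsample(full: EventMatrix, medians: pd.DataFrame, markers: list[str]) -> np.ndarray:
    """Assign every cell to the nearest cluster median (L1); ties go to the
    lower cluster id."""
    X = full.values[:, full.marker_index(markers)]
    M = medians[markers].to_numpy()
    ids = np.asarray(medians.index)
    order = np.argsort(ids, kind="stable")
    M, ids = M[order], ids[order]
    out = np.empty(X.shape[0], dtype=np.int64)
    for start in range(0, X.shape[0], _CHUNK):
        d = cdist(X[start : start + _CHUNK], M, metric="cityblock")
        # exact-tie tolerance: treat distances within 1e-9 of the row minimum as tied
        dmin = d.min(axis=1, keepdims=True)
        tied = d <= dmin + 1e-9
        out[start : start + _CHUNK] = ids[tied.argmax(axis=1)]
    return out


def abundance_table(assignment: np.ndarray, cell_sample: np.ndarray, k: int) -> pd.DataFrame:
    """Clusters x samples table of per-sample cell fractions (columns sum to 1).

    Clusters that received no cells anywhere are retained with zero
    abundance so cluster ids stay stable.
    """
    if assignment.shape != cell_sample.shape:
        raise InputError("assignment and sample labels differ in length")
    df = pd.crosstab(pd.Series(assignment, name="cluster"), pd.Series(cell_sample, name="sample"))
    df = df.reindex(range(1, k + 1), fill_value=0)
    return df / df.sum(axis=0)


def save_tree(tree: SpadeTree, out_dir) -> None:
    """Persist a tree as delimited text + JSON metadata (assignment per cell,
    medians, MST edges)."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"sample": tree.cell_sample, "cluster": tree.assignment}).to_csv(
        out / "assignment.tsv", sep="\t", index=False
    )
    tree.medians.to_csv(out / "medians.csv")
    tree.pooled_medians.to_csv(out / "pooled_medians.csv")
    tree.pooled_medians_all.to_csv(out / "pooled_medians_all.csv")
    pd.DataFrame(tree.mst_edges, columns=["a", "b", "weight"]).to_csv(out / "mst.csv", index=False)
    (out / "meta.json").write_text(
        json.dumps({"k": tree.k, "markers": tree.markers, "sample_order": tree.sample_order}, indent=1)
    )


def load_tree(in_dir) -> SpadeTree:
    import json
    from pathlib import Path

    d = Path(in_dir)
    meta = json.loads((d / "meta.json").read_text())
    assign = pd.read_csv(d / "assignment.tsv", sep="\t")
    medians = pd.read_csv(d / "medians.csv", index_col=[0, 1])
    edges = [
        (int(r.a), int(r.b), float(r.weight)) for r in pd.read_csv(d / "mst.csv").itertuples()
    ]
    return SpadeTree(
        k=int(meta["k"]),
        assignment=assign["cluster"].to_numpy(np.int64),
        cell_sample=assign["sample"].to_numpy(object),
        medians=medians,
        pooled_medians=pd.read_csv(d / "pooled_medians.csv", index_col=0),
        pooled_medians_all=pd.read_csv(d / "pooled_medians_all.csv", index_col=0),
        mst_edges=edges,
        markers=list(meta["markers"]),
        sample_order=list(meta["sample_order"]),
    )


def run_spade(
    samples: SampleSet | list[EventMatrix],
    markers: list[str],
    k: int,
    target_fraction: float = 0.05,
    alpha: float = 5.0,
    seed: int = 0,
    ref_size: int = 2000,
) -> SpadeTree:
    """Full SPADE run over the concatenated cohort; see the module docstring."""
    sample_list = list(samples.samples) if isinstance(samples, SampleSet) else list(samples)
    pooled = concatenate(sample_list)
    dens = estimate_density(pooled, markers, alpha=alpha, seed=seed, ref_size=ref_size)
    sub, _ = downsample(pooled, dens, target_fraction, seed=seed + 1)
    if sub.n_cells < k:  # tiny cohorts: fall back to clustering everything
        sub = pooled
    medians, _ = cluster(sub, markers, k, seed=seed)
    assignment = upsample(pooled, medians, markers)
    all_markers = list(pooled.markers)
    frame = pd.DataFrame(pooled.values, columns=all_markers)
    frame["cluster"] = assignment
    frame["sample"] = pooled.provenance
    per_cs = frame.groupby(["cluster", "sample"], sort=True).median()
    pooled_all = frame.drop(columns="sample").groupby("cluster").median()
    edges = build_mst(medians) if len(medians) >= 2 else []
    return SpadeTree(
        k=k,
        assignment=assignment,
        cell_sample=np.asarray(pooled.provenance),
        medians=per_cs,
        pooled_medians=medians,
        pooled_medians_all=pooled_all,
        mst_edges=edges,
        markers=list(markers),
        sample_order=[s.sample_id for s in sample_list],
    )
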