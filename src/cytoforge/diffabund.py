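"""Differential cluster abundance between clinical groups.

Each cluster's abundance is the fraction of a sample's cells assigned to it.
A cluster's *enrichment trend* is simply which group has the larger mean
abundance; significance comes from a non-parametric permutation test on the
group labels with the absolute difference of group means as the statistic.
With 9 RA and 5 healthy samples the full set of C(14,5) = 2002 relabelings
is enumerable, so the exact null distribution is used whenever the number
of distinct relabelings is at most 10^6; otherwise Monte-Carlo relabeling
is used with the add-one correction so p > 0 always.

No multiple-testing correction is applied by default; Benjamini-Hochberg is
available behind ``correct="bh"``.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .errors import DomainError, InputError

EXACT_LIMIT = 10**6
# Relative slack when counting permutation statistics >= the observed one, so
# exactly-tied relabelings (e.g. the label swap of the identity) are counted
# despite floating-point noise.
_TIE_RTOL = 1e-9


def permutation_test(
    x,
    y,
    mode: str = "auto",
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a difference in group means.

    The statistic is ``|mean(x) - mean(y)|``.  ``mode="exact"`` enumerates
    all distinct relabelings of the pooled values into groups of the
    original sizes (refusing when there are more than 10^6 and pointing to
    Monte Carlo); ``"monte_carlo"`` draws ``n_perm`` random relabelings;
    ``"auto"`` picks exact when feasible.  The observed labeling counts
    toward the numerator and denominator, so the returned p is in (0, 1].
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 1 or y.size < 1:
        raise DomainError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    observed = abs(x.mean() - y.mean())
    cutoff = observed - _TIE_RTOL * (abs(observed) + pooled.std() + 1.0)

    n_exact = comb(n, nx)
    if mode == "auto":
        mode = "exact" if n_exact <= EXACT_LIMIT else "monte_carlo"
    if mode == "exact":
        if n_exact > EXACT_LIMIT:
            raise DomainError(
                f"exact mode would enumerate {n_exact} relabelings (> {EXACT_LIMIT}); "
                "use mode='monte_carlo'"
            )
        total = pooled.sum()
        count = 0
        # |mean(xperm) - mean(yperm)| depends only on the permuted x-group sum
        for idx in combinations(range(n), nx):
            sx = pooled[list(idx)].sum()
            stat = abs(sx / nx - (total - sx) / (n - nx))
            if stat >= cutoff:
                count += 1
        return count / n_exact
    if mode == "monte_carlo":
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        count = 0
        for _ in range(int(n_perm)):
            perm = rng.permutation(pooled)
            stat = abs(perm[:nx].mean() - perm[nx:].mean())
            if stat >= cutoff:
                count += 1
        return (1 + count) / (1 + int(n_perm))
    raise DomainError(f"unknown mode {mode!r}")


def enrichment_trend(abundance: pd.DataFrame, groups: dict[str, str]) -> pd.Series:
    """Per-cluster trend: which group has the larger mean abundance.

    *abundance* is clusters x samples (fractions); *groups* maps each sample
    column to ``"RA"`` or ``"healthy"``.  Exact equality of group means is
    labeled ``"tied"``.
    """
    missing = [s for s in abundance.columns if s not in groups]
    if missing:
        raise InputError(f"group label missing for samples: {missing}")
    ra_cols = [s for s in abundance.columns if groups[s] == "RA"]
    hc_cols = [s for s in abundance.columns if groups[s] == "healthy"]
    if not ra_cols or not hc_cols:
        raise InputError("both groups must be represented among the samples")
    ra_mean = abundance[ra_cols].mean(axis=1)
    hc_mean = abundance[hc_cols].mean(axis=1)
    trend = np.where(ra_mean > hc_mean, "RA-enriched", np.where(ra_mean < hc_mean, "healthy-enriched", "tied"))
    return pd.Series(trend, index=abundance.index, name="trend")


def cluster_enrichment(
    abundance: pd.DataFrame,
    groups: dict[str, str],
    mode: str = "auto",
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    correct: str | None = None,
) -> pd.DataFrame:
    """Trend + permutation p-value per cluster.

    Returns a DataFrame indexed by cluster with columns ``ra_mean``,
    ``healthy_mean``, ``trend``, ``p_value``, ``significant``.  Optional
    ``correct="bh"`` replaces the significance call with a
    Benjamini-Hochberg decision at *alpha* (p-values themselves are
    reported unadjusted).
    """
    trends = enrichment_trend(abundance, groups)
    ra_cols = [s for s in abundance.columns if groups[s] == "RA"]
    hc_cols = [s for s in abundance.columns if groups[s] == "healthy"]
    rows = []
    for i, cluster in enumerate(abundance.index):
        p = permutation_test(
            abundance.loc[cluster, ra_cols].to_numpy(),
            abundance.loc[cluster, hc_cols].to_numpy(),
            mode=mode,
            n_perm=n_perm,
            seed=int(seed) + i,
        )
        rows.append(p)
    out = pd.DataFrame(
        {
            "ra_mean": abundance[ra_cols].mean(axis=1),
            "healthy_mean": abundance[hc_cols].mean(axis=1),
            "trend": trends,
            "p_value": rows,
        },
        index=abundance.index,
    )
    if correct == "bh":
        from statsmodels.stats.multitest import multipletests

        out["significant"] = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")[0]
    elif correct is None:
        out["significant"] = out["p_value"] < alpha
    else:
        raise DomainError(f"unknown correction {correct!r}")
    return out


def summarize(trends: pd.Series, annotation: pd.Series) -> pd.DataFrame:
    """Per-cell-type cluster composition and RA-enrichment fractions.

    Returns a DataFrame indexed by cell type with ``fraction_of_clusters``
    (fractions sum to 1 over types present) and ``fraction_ra_enriched``
    (share of that type's clusters trending RA), plus an ``overall`` row
    giving the global RA-enriched fraction.
    """
    missing = trends.index.difference(annotation.index)
    if len(missing):
        raise InputError(f"annotation missing for clusters: {list(missing)[:5]}")
    ann = annotation.loc[trends.index]
    total = len(trends)
    rows = {}
    for cell_type in sorted(ann.unique()):
        mask = ann == cell_type
        rows[cell_type] = {
            "fraction_of_clusters": mask.sum() / total,
            "fraction_ra_enriched": (trends[mask] == "RA-enriched").mean(),
        }
    rows["overall"] = {
        "fraction_of_clusters": 1.0,
        "fraction_ra_enriched": (trends == "RA-enriched").mean(),
    }
    return pd.DataFrame.from_dict(rows, orient="index")
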