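"""TLR-stimulation cytokine response quantification.

After whole-blood stimulation with TLR agonists (LPS / R848 / poly(I:C)),
the stimulation arm re-clusters all profiles at k = 100 on the 20-marker
surface set, annotates clusters to cell types, and scores, per population
and sample, the percentage of cells positive for each intracellular
cytokine (MIP-1b, TNF-a, IL-8).

Positivity is control-referenced: the threshold for a (population,
cytokine) is the 99th percentile of the cytokine's transformed intensity
among that population's cells in the matched PBS control sample, falling
back to the pooled control cells of that population when the per-sample
population is too small (< 100 cells).  By construction a control sample
scored against itself sits near 1% positive.

Stimulated-vs-control and RA-vs-healthy differences are assessed with the
exact permutation test on per-sample percentages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diffabund import permutation_test
from .errors import InputError, SelectionError
from .io import EventMatrix
from .panel import CYTOKINES

MIN_CONTROL_CELLS = 100
DEFAULT_PERCENTILE = 99.0


def positivity_threshold(
    control_cells: EventMatrix | np.ndarray, cytokine: str, percentile: float = DEFAULT_PERCENTILE
) -> float:
    """Positivity threshold: the given percentile of the cytokine's
    transformed intensity among control cells of one population."""
    if isinstance(control_cells, EventMatrix):
        col = control_cells.column(cytokine)
    else:
        col = np.asarray(control_cells, dtype=np.float64)
    if col.size < MIN_CONTROL_CELLS:
        raise SelectionError(
            f"only {col.size} control cells for {cytokine} threshold (need >= {MIN_CONTROL_CELLS})"
        )
    return float(np.percentile(col, percentile))


def percent_positive(values: np.ndarray, threshold: float) -> float:
    """100 x fraction of intensities strictly above the threshold."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return float("nan")
    return 100.0 * float((values > threshold).mean())


def response_table(
    samples: list[EventMatrix],
    cell_population: np.ndarray,
    cell_sample: np.ndarray,
    cell_condition: np.ndarray,
    populations: list[str],
    cytokines: list[str] | None = None,
    percentile: float = DEFAULT_PERCENTILE,
) -> pd.DataFrame:
    """Percent-positive per (population, cytokine, sample, condition).

    *cell_population*, *cell_sample* and *cell_condition* are per-cell
    labels over the concatenation of *samples* (tree assignment mapped
    through cluster annotation).  Thresholds come from each sample's own
    PBS control, falling back to the pooled control for that population;
    empty (population, sample) combinations are recorded as NaN.
    """
    cytokines = cytokines or list(CYTOKINES)
    pooled_values = np.vstack([s.values for s in samples])
    markers = samples[0].markers
    midx = {m: i for i, m in enumerate(markers)}
    missing = [c for c in cytokines if c not in midx]
    if missing:
        raise InputError(f"cytokines not in panel: {missing}")
    cell_population = np.asarray(cell_population, dtype=object)
    cell_sample = np.asarray(cell_sample)
    cell_condition = np.asarray(cell_condition)
    if not (len(cell_population) == len(cell_sample) == len(cell_condition) == len(pooled_values)):
        raise InputError("per-cell label arrays are not aligned with the cells")

    sample_ids = list(dict.fromkeys(cell_sample))
    rows = []
    for pop in populations:
        pop_mask = cell_population == pop
        pooled_ctrl = pop_mask & (cell_condition == "unstimulated")
        for cyt in cytokines:
            col = pooled_values[:, midx[cyt]]
            pooled_thr = (
                positivity_threshold(col[pooled_ctrl], cyt, percentile)
                if pooled_ctrl.sum() >= MIN_CONTROL_CELLS
                else np.nan
            )
            for sid in sample_ids:
                ctrl_mask = pop_mask & (cell_sample == sid) & (cell_condition == "unstimulated")
                if ctrl_mask.sum() >= MIN_CONTROL_CELLS:
                    thr = float(np.percentile(col[ctrl_mask], percentile))
                elif np.isfinite(pooled_thr):
                    thr = pooled_thr
                else:
                    thr = np.nan
                for condition in ("unstimulated", "TLR_stimulated"):
                    mask = pop_mask & (cell_sample == sid) & (cell_condition == condition)
                    if not mask.any() or not np.isfinite(thr):
                        pct = np.nan
                    else:
                        pct = percent_positive(col[mask], thr)
                    rows.append(
                        {
                            "population": pop,
                            "cytokine": cyt,
                            "sample": sid,
                            "condition": condition,
                            "percent_positive": pct,
                            "threshold": thr,
                        }
                    )
    return pd.DataFrame(rows)


def compare_response(
    results: pd.DataFrame, groups: dict[str, str], mode: str = "auto", seed: int = 0
) -> pd.DataFrame:
    """Per (population, cytokine): stimulated-vs-control p and RA-vs-healthy
    p among stimulated samples (permutation tests on per-sample percentages).

    Samples lacking either condition are excluded with a warning.
    """
    need = {"population", "cytokine", "sample", "condition", "percent_positive"}
    if not need <= set(results.columns):
        raise InputError(f"results table missing columns: {sorted(need - set(results.columns))}")
    out = []
    for (pop, cyt), sub in results.groupby(["population", "cytokine"]):
        wide = sub.pivot_table(
            index="sample", columns="condition", values="percent_positive", aggfunc="first"
        )
        for cond in ("unstimulated", "TLR_stimulated"):
            if cond not in wide.columns:
                wide[cond] = np.nan
        paired = wide.dropna()
        dropped = sorted(set(wide.index) - set(paired.index))
        if dropped:
            warnings.warn(
                f"{pop}/{cyt}: unpaired or empty samples excluded: {dropped}", stacklevel=2
            )
        p_stim = (
            permutation_test(
                paired["TLR_stimulated"].to_numpy(), paired["unstimulated"].to_numpy(),
                mode=mode, seed=seed,
            )
            if len(paired) >= 2
            else np.nan
        )
        stim = paired["TLR_stimulated"]
        ra = stim[[groups.get(s) == "RA" for s in stim.index]]
        hc = stim[[groups.get(s) == "healthy" for s in stim.index]]
        p_group = (
            permutation_test(ra.to_numpy(), hc.to_numpy(), mode=mode, seed=seed)
            if len(ra) >= 2 and len(hc) >= 2
            else np.nan
        )
        out.append(
            {
                "population": pop,
                "cytokine": cyt,
                "mean_pct_control": float(paired["unstimulated"].mean()) if len(paired) else np.nan,
                "mean_pct_stimulated": float(stim.mean()) if len(paired) else np.nan,
                "p_stim_vs_control": p_stim,
                "p_ra_vs_healthy": p_group,
            }
        )
    return pd.DataFrame(out)
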