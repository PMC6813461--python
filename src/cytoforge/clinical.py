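"""Clinical covariates and rank-based correlation.

The patient table mirrors the study cohort's published characteristics:
per-patient age range, current treatments, disease duration in months,
DAS28 (28-joint Disease Activity Score; > 3.2 means active disease), and
anti-CCP / erosion / rheumatoid-factor flags.  Healthy donors carry NA for
every clinical field and are excluded from correlations automatically.

Correlation is Spearman's rank correlation, matching R's ``cor.test``
behaviour at small n: with no ties and n <= 10 the two-sided p-value comes
from exact enumeration of the rank-statistic null (all n! rank orders of
the S statistic, S = sum of squared rank differences); with ties, or larger
n, mid-ranks are used and p comes from the Student-t approximation
``t = rho * sqrt((n-2) / (1-rho^2))`` with n-2 degrees of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diffabund import permutation_test
from .errors import DomainError, InputError

EXACT_N_LIMIT = 10

CLINICAL_COLUMNS = [
    "Patients",
    "Age range (years)",
    "Current treatments",
    "Disease duration (months)",
    "DAS28",
    "Anti-CCP",
    "Erosion",
    "RF",
]


def table1() -> pd.DataFrame:
    """The verbatim published RA patient characteristics table (9 patients).

    Internal columns: patient_id, group, age_range, treatments,
    duration_months, das28, anti_ccp, erosion, rf.
    """
    with resources.files("cytoforge.data").joinpath("table1.csv").open() as fh:
        raw = pd.read_csv(fh, dtype=str, keep_default_na=False)
    return _from_published(raw)


def _from_published(raw: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise InputError(f"clinical table missing columns: {missing}")
    df = pd.DataFrame(
        {
            "patient_id": raw["Patients"],
            "group": "RA",
            "age_range": raw["Age range (years)"],
            "treatments": raw["Current treatments"],
            "duration_months": raw["Disease duration (months)"].astype(int),
            "das28": raw["DAS28"].astype(float),
            "anti_ccp": raw["Anti-CCP"],
            "erosion": raw["Erosion"],
            "rf": raw["RF"],
        }
    )
    if (df["duration_months"] <= 0).any():
        raise InputError("disease duration must be positive for RA patients")
    return df


def to_published(clin: pd.DataFrame) -> pd.DataFrame:
    """Render the internal clinical frame with the published column names."""
    ra = clin[clin["group"] == "RA"]
    return pd.DataFrame(
        {
            "Patients": ra["patient_id"],
            "Age range (years)": ra["age_range"],
            "Current treatments": ra["treatments"],
            "Disease duration (months)": ra["duration_months"].astype(int),
            "DAS28": ra["das28"],
            "Anti-CCP": ra["anti_ccp"],
            "Erosion": ra["erosion"],
            "RF": ra["rf"],
        }
    )


def load_clinical(path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    return _from_published(raw)


def has_treatment(clin: pd.DataFrame, treatment: str) -> pd.Series:
    """Boolean per patient: is *treatment* among the current treatments (substring, case-insensitive)."""
    return clin["treatments"].str.lower().str.contains(treatment.lower(), regex=False)


@dataclass
class CorrelationResult:
    rho: float
    p_two_sided: float
    method: str  # exact_enumeration | t_approximation
    n: int
    ties_present: bool
    covariate: str | None = None


@lru_cache(maxsize=None)
def _exact_s_distribution(n: int) -> np.ndarray:
    """counts[s] = number of rank permutations of 1..n with S = sum (i - perm_i)^2 = s."""
    base = np.arange(1, n + 1)
    max_s = (n**3 - n) // 3
    counts = np.zeros(max_s + 1, dtype=np.int64)
    chunk: list = []
    for perm in itertools.permutations(range(1, n + 1)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            s = ((np.asarray(chunk) - base) ** 2).sum(axis=1)
            counts += np.bincount(s, minlength=max_s + 1)
            chunk = []
    if chunk:
        s = ((np.asarray(chunk) - base) ** 2).sum(axis=1)
        counts += np.bincount(s, minlength=max_s + 1)
    return counts


def exact_spearman_p(s_obs: float, n: int) -> float:
    """Two-sided exact p for the Spearman S statistic at sample size n (no ties).

    ``p = min(1, 2 * min(P(S <= s), P(S >= s)))`` over the uniform null on
    all n! rank orders.
    """
    if n > EXACT_N_LIMIT:
        raise DomainError(f"exact enumeration limited to n <= {EXACT_N_LIMIT}")
    counts = _exact_s_distribution(n)
    total = factorial(n)
    s_idx = int(round(s_obs))
    lower = counts[: s_idx + 1].sum() / total
    upper = counts[s_idx:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def t_approx_p(rho: float, n: int) -> float:
    """Two-sided p from the Student-t approximation of the Spearman statistic."""
    if n < 3:
        raise DomainError("need n >= 3")
    if abs(rho) >= 1.0:
        return float(np.nextafter(0.0, 1.0))
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with R-compatible small-sample p-values."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise DomainError("need at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InputError("missing values are not allowed")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DomainError("correlation undefined for a constant input")
    rx = sps.rankdata(x)  # mid-ranks
    ry = sps.rankdata(y)
    ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if not ties and n <= EXACT_N_LIMIT:
        s_obs = float(((rx - ry) ** 2).sum())
        return CorrelationResult(rho, exact_spearman_p(s_obs, n), "exact_enumeration", n, False)
    return CorrelationResult(rho, t_approx_p(rho, n), "t_approximation", n, ties)


def correlate_abundance(subpop_pct, clin: pd.DataFrame, covariate: str) -> CorrelationResult:
    """Correlate per-patient subpopulation percentages with a clinical covariate.

    *subpop_pct* is either a mapping/Series keyed by RA patient_id, or an
    array aligned to the RA rows of *clin* in order.  Healthy donors are
    excluded.  *covariate* is ``duration_months`` or ``das28``.
    """
    if covariate not in ("duration_months", "das28"):
        raise InputError(f"unknown covariate {covariate!r}")
    ra = clin[clin["group"] == "RA"]
    if isinstance(subpop_pct, dict):
        subpop_pct = pd.Series(subpop_pct)
    if isinstance(subpop_pct, pd.Series):
        missing = [p for p in ra["patient_id"] if p not in subpop_pct.index]
        if missing:
            raise InputError(f"subpopulation percentages missing for patients: {missing}")
        values = subpop_pct.loc[ra["patient_id"]].to_numpy(dtype=np.float64)
    else:
        values = np.asarray(subpop_pct, dtype=np.float64)
        if values.size != len(ra):
            raise InputError(
                f"{values.size} percentages for {len(ra)} RA patients"
            )
    result = spearman(values, ra[covariate].to_numpy(dtype=np.float64))
    result.covariate = covariate
    return result


def group_compare(subpop_pct, groups, mode: str = "exact", n_perm: int = 10_000, seed: int = 0) -> float:
    """Exact permutation comparison of subpopulation percentages between two groups."""
    values = np.asarray(subpop_pct, dtype=np.float64)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise InputError("values and group labels differ in length")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise InputError(f"need exactly two groups, got {list(levels)}")
    return permutation_test(
        values[groups == levels[0]], values[groups == levels[1]], mode=mode, n_perm=n_perm, seed=seed
    )
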