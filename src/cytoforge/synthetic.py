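"""Synthetic multi-sample CyTOF cohort generator with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a cohort of 9 RA and 5 healthy whole-blood samples measured on the
33-marker panel, composed of the major leukocyte populations at blood-norm
abundances, plus two planted disease-linked subpopulations —

* a CD11b(low) CD16(high) neutrophil subpopulation whose within-neutrophil
  fraction rises with disease duration in RA patients (logit-linear link),
  present at a small baseline in healthy donors; and
* a CD11a(high) Granzyme-B(high) T-cell subpopulation present in a random
  subset of RA patients (Bernoulli per patient, mirroring a bimodal
  group-A/group-B split) whose size falls with DAS28.

Marker intensities are Gaussian on the arcsinh scale around per-population
modes, zero-inflated (mass-cytometry dropout), truncated at zero, with a
per-sample Gaussian batch shift.  Under TLR stimulation a configured
responder fraction of monocytes/cDC/pDC shifts its MIP-1b, TNF-a and IL-8
modes upward; all other populations never produce cytokines.  Emitted
samples are *raw* ion counts (``sinh`` of the latent arcsinh values times
the cofactor), so the pipeline's own arcsinh transform recovers the latent
scale exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clinical import table1
from .errors import DomainError, SpecError
from .io import EventMatrix, SampleSet
from .panel import CYTOKINES, MarkerPanel, default_panel

# Canonical arcsinh-scale expression modes.
LEVELS = {"neg": 0.15, "low": 1.2, "med": 2.5, "high": 4.0, "vhigh": 5.5}
DEFAULT_SD = 0.4
ZERO_INFLATION_NEG = 0.30
ZERO_INFLATION_POS = 0.02
CYTOKINE_SHIFT_SD = 4.0  # stimulation shifts responder cytokine modes by this many SDs

# Marker signature per population; unlisted markers sit at the "neg" mode.
SIGNATURES: dict[str, dict[str, str]] = {
    "neutrophil": {"CD66": "high", "CD16": "high", "CD11b": "high", "CD32": "high",
                   "CD11a": "med", "TLR2": "med", "CXCR4": "med", "CD45": "med"},
    # planted RA subpopulation: neutrophil signature with CD11b low, CD16 very high
    "neutrophil_cd11blow_cd16high": {"CD66": "high", "CD16": "vhigh", "CD11b": "low",
                                     "CD32": "high", "CD11a": "med", "TLR2": "med",
                                     "CXCR4": "med", "CD45": "med"},
    "t_cell": {"CD3": "high", "CD28": "high", "CD11a": "med", "CXCR4": "med", "CD45": "high"},
    # planted RA subpopulation: T signature with CD11a and Granzyme B very high
    "t_cd11ahigh_gzmbhigh": {"CD3": "high", "CD11a": "vhigh", "GranzymeB": "vhigh",
                             "Perforin": "high", "CCR5": "high", "CD28": "low", "CD45": "high"},
    "b_cell": {"CD19": "high", "HLADR": "high", "CD23": "med", "CXCR4": "med", "CD45": "high"},
    "nk": {"CD16": "high", "GranzymeB": "med", "Perforin": "high", "CD11a": "med", "CD45": "high"},
    "monocyte": {"CD14": "high", "HLADR": "high", "CD11b": "high", "CD11c": "med",
                 "CD64": "high", "CD32": "med", "TLR2": "med", "CD45": "high"},
    "cdc": {"CD11c": "high", "HLADR": "high", "CD86": "med", "CD45": "high"},
    "pdc": {"CD123": "high", "HLADR": "high", "CXCR4": "med", "CD45": "med"},
    "basophil": {"CD123": "high", "CD32": "med", "CD45": "med"},
}

# Blood-norm baseline abundances (fractions of leukocytes); subpopulations are
# carved out of their parents at sampling time, so they carry base 0 here.
BASE_FRACTIONS = {
    "neutrophil": 0.55,
    "t_cell": 0.25,
    "monocyte": 0.08,
    "b_cell": 0.05,
    "nk": 0.05,
    "cdc": 0.012,
    "pdc": 0.004,
    "basophil": 0.004,
}

RESPONDER_POPULATIONS = ("monocyte", "cdc", "pdc")


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(z: float) -> float:
    return float(1.0 / (1.0 + np.exp(-z)))


@dataclass
class PopulationSpec:
    """One population's abundance and per-marker (mean, sd) arcsinh modes."""

    name: str
    base_fraction: float
    marker_modes: dict[str, tuple[float, float]]
    zero_inflation: dict[str, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_fraction <= 1.0):
            raise SpecError(f"{self.name}: base_fraction outside [0,1]")
        for m, (_, sd) in self.marker_modes.items():
            if sd <= 0:
                raise SpecError(f"{self.name}: sd must be positive for marker {m}")
        for m, z in self.zero_inflation.items():
            if not (0.0 <= z <= 1.0):
                raise SpecError(f"{self.name}: zero-inflation outside [0,1] for {m}")


@dataclass
class SubpopLink:
    """Logit-linear link of a planted subpopulation's within-parent fraction to a covariate.

    For an RA patient with covariate value c the within-parent fraction is
    ``sigmoid(intercept + slope * c + eps)`` with ``eps ~ N(0, noise_sd)``,
    gated by a per-patient presence Bernoulli; healthy donors sit at
    ``healthy_fraction``.
    """

    name: str
    parent: str
    covariate: str
    slope: float
    intercept: float
    noise_sd: float = 0.0
    healthy_fraction: float = 0.0
    presence_prob: float = 1.0


@dataclass
class CohortSpec:
    n_ra: int = 9
    n_healthy: int = 5
    cells_per_sample: int = 10_000
    populations: list[PopulationSpec] = field(default_factory=list)
    subpop_links: list[SubpopLink] = field(default_factory=list)
    batch_sd: float = 0.05
    responder_fraction: float = 0.4
    stimulated_pairs: bool = False
    cofactor: float = 5.0
    seed: int = 0
    clinical_fixture: bool = True

    def __post_init__(self) -> None:
        if self.n_ra < 1 or self.n_healthy < 0 or self.cells_per_sample < 1:
            raise SpecError("cohort sizes must be positive")
        names = {p.name for p in self.populations}
        if len(names) != len(self.populations):
            raise SpecError("duplicate population names")
        total = sum(p.base_fraction for p in self.populations)
        if self.populations and abs(total - 1.0) > 1e-9:
            raise SpecError(f"population base fractions sum to {total}, not 1")
        for link in self.subpop_links:
            if link.parent not in names or link.name not in names:
                raise SpecError(f"link {link.name!r} references unknown populations")
            if link.covariate not in ("duration_months", "das28"):
                raise SpecError(f"link {link.name!r}: unknown covariate {link.covariate!r}")


@dataclass
class GroundTruth:
    """Planted truth: per-cell labels, per-sample subpop fractions, covariates used."""

    labels: dict[tuple[str, str], np.ndarray]  # (sample_id, condition) -> per-cell population
    planted_fractions: pd.DataFrame  # samples x subpop (within-parent fraction)
    clinical: pd.DataFrame


def _population_spec(name: str) -> PopulationSpec:
    sig = SIGNATURES[name]
    modes, zi = {}, {}
    for marker in default_panel().markers:
        level = sig.get(marker, "neg")
        modes[marker] = (LEVELS[level], DEFAULT_SD)
        zi[marker] = ZERO_INFLATION_NEG if level == "neg" else ZERO_INFLATION_POS
    return PopulationSpec(name, BASE_FRACTIONS.get(name, 0.0), modes, zi)


def default_cohort_spec(**overrides) -> CohortSpec:
    """The default study-shaped cohort: 9 RA + 5 healthy, 10k cells/sample.

    The neutrophil subpopulation link is calibrated so the within-neutrophil
    fraction averages roughly a third in RA (rising from ~18% at 28 months
    to ~54% at 304 months of disease) against a ~9% healthy baseline; the
    T-cell subpopulation is present in a random ~5/9 of RA patients with a
    negative DAS28 link and a ~3% healthy baseline.
    """
    populations = [_population_spec(n) for n in SIGNATURES]
    links = [
        SubpopLink(
            name="neutrophil_cd11blow_cd16high",
            parent="neutrophil",
            covariate="duration_months",
            slope=0.006,
            intercept=_logit(0.337) - 0.006 * 166.0,
            noise_sd=0.2,
            healthy_fraction=0.092,
            presence_prob=1.0,
        ),
        SubpopLink(
            name="t_cd11ahigh_gzmbhigh",
            parent="t_cell",
            covariate="das28",
            slope=-0.5,
            intercept=_logit(0.20) + 0.5 * 3.5,
            noise_sd=0.3,
            healthy_fraction=0.033,
            presence_prob=5.0 / 9.0,
        ),
    ]
    spec = CohortSpec(populations=populations, subpop_links=links)
    return replace(spec, **overrides) if overrides else spec


_TREATMENT_POOL = [
    ("Methotrexate", 5 / 9), ("Prednisone", 2 / 9), ("Tocilizumab", 2 / 9),
    ("Rituximab", 2 / 9), ("Etanercept", 1 / 9),
    ("Nonsteroidal anti-inflammatory drugs", 1 / 9),
    ("Hydroxychloroquine", 1 / 9), ("Salazopyrine", 1 / 9),
]
_AGE_RANGES = ["36-40", "40-45", "50-55", "56-60", "71-75", "80-85"]
_FLAG_FREQS = {"anti_ccp": (8, 0, 1), "erosion": (7, 1, 1), "rf": (6, 1, 2)}  # yes/no/NA out of 9
DURATION_RANGE = (28, 304)
DAS28_RANGE = (1.89, 6.85)


def simulate_clinical(n_ra: int, seed: int = 0, fixture: bool = True) -> pd.DataFrame:
    """Simulate an RA clinical table; returns the verbatim published rows
    when ``n_ra == 9`` and *fixture* is on.

    Sampled columns: disease duration uniform over the published extrema
    [28, 304] months, DAS28 uniform over [1.89, 6.85], treatments and
    serology flags drawn from the published empirical frequencies.
    """
    if n_ra < 1:
        raise DomainError("n_ra must be >= 1")
    if fixture and n_ra == 9:
        return table1()
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 101])
    rows = []
    for i in range(n_ra):
        treatments = [name for name, f in _TREATMENT_POOL if rng.random() < f]
        if not treatments:
            treatments = ["Methotrexate"]
        flags = {}
        for col, (yes, no, na) in _FLAG_FREQS.items():
            flags[col] = rng.choice(["Yes", "No", "NA"], p=np.array([yes, no, na]) / 9.0)
        rows.append(
            {
                "patient_id": f"PAT-{i + 1}",
                "group": "RA",
                "age_range": rng.choice(_AGE_RANGES),
                "treatments": ", ".join(treatments),
                "duration_months": int(rng.integers(DURATION_RANGE[0], DURATION_RANGE[1] + 1)),
                "das28": float(np.round(rng.uniform(*DAS28_RANGE), 2)),
                **flags,
            }
        )
    return pd.DataFrame(rows)


def _healthy_rows(n_healthy: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [f"HD-{i + 1}" for i in range(n_healthy)],
            "group": "healthy",
            "age_range": "NA",
            "treatments": "NA",
            "duration_months": np.nan,
            "das28": np.nan,
            "anti_ccp": "NA",
            "erosion": "NA",
            "rf": "NA",
        }
    )


def _sample_fractions(
    spec: CohortSpec, patient: pd.Series, rng: np.random.Generator, presence: dict[str, bool]
) -> tuple[dict[str, float], dict[str, float]]:
    """Effective per-population fractions for one sample, plus the planted
    within-parent subpop fractions (the ground truth)."""
    fractions = {p.name: p.base_fraction for p in spec.populations}
    planted: dict[str, float] = {}
    for link in spec.subpop_links:
        if patient["group"] == "RA":
            if not presence.get(link.name, True):
                f = 0.0
            else:
                cov = float(patient[link.covariate])
                eps = rng.normal(0.0, link.noise_sd) if link.noise_sd > 0 else 0.0
                f = _sigmoid(link.intercept + link.slope * cov + eps)
        else:
            f = link.healthy_fraction
        planted[link.name] = f
        parent_base = fractions[link.parent]
        fractions[link.name] = f * parent_base
        fractions[link.parent] = (1.0 - f) * parent_base
    return fractions, planted


def simulate_sample(
    spec: CohortSpec,
    patient: pd.Series,
    condition: str = "unstimulated",
    seed: int = 0,
    panel: MarkerPanel | None = None,
) -> tuple[EventMatrix, np.ndarray, dict[str, float]]:
    """Simulate one sample.

    Returns ``(events, labels, planted_fractions)`` where *events* is a raw
    EventMatrix, *labels* the per-cell ground-truth population names, and
    *planted_fractions* the within-parent subpopulation fractions used.
    """
    panel = panel or default_panel()
    cond_idx = {"unstimulated": 0, "TLR_stimulated": 1}[condition]
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 7, cond_idx])
    # patient-level randomness (subpop presence, link noise) must not depend
    # on the condition so stimulated/control mates share their ground truth
    patient_rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 13])
    presence = {
        link.name: bool(patient_rng.random() < link.presence_prob) for link in spec.subpop_links
    }
    fractions, planted = _sample_fractions(spec, patient, patient_rng, presence)
    pops = list(fractions)
    probs = np.array([fractions[p] for p in pops])
    probs = probs / probs.sum()
    n = spec.cells_per_sample
    labels = rng.choice(pops, size=n, p=probs)

    spec_by_name = {p.name: p for p in spec.populations}
    values = np.empty((n, len(panel)), dtype=np.float64)
    batch = rng.normal(0.0, spec.batch_sd, size=len(panel)) if spec.batch_sd > 0 else np.zeros(len(panel))
    stimulated = condition == "TLR_stimulated"
    responder = np.zeros(n, dtype=bool)
    if stimulated:
        in_responder_pop = np.isin(labels, RESPONDER_POPULATIONS)
        responder = in_responder_pop & (rng.random(n) < spec.responder_fraction)

    cytokine_idx = {m: j for j, m in enumerate(panel.markers) if m in CYTOKINES}
    dropout = np.zeros_like(values, dtype=bool)
    for pop in pops:
        mask = labels == pop
        if not mask.any():
            continue
        pspec = spec_by_name[pop]
        k = int(mask.sum())
        for j, marker in enumerate(panel.markers):
            mean, sd = pspec.marker_modes.get(marker, (LEVELS["neg"], DEFAULT_SD))
            col = rng.normal(mean, sd, size=k)
            zi = pspec.zero_inflation.get(marker, ZERO_INFLATION_NEG)
            zmask = np.zeros(k, dtype=bool)
            if zi > 0:
                zmask = rng.random(k) < zi
                col[zmask] = 0.0
            values[mask, j] = col
            dropout[np.flatnonzero(mask)[zmask], j] = True
    if stimulated and responder.any():
        for marker, j in cytokine_idx.items():
            shift = CYTOKINE_SHIFT_SD * DEFAULT_SD
            vals = values[responder, j]
            # re-express dropout cells at the shifted mode rather than shifting zeros
            base_mean, base_sd = LEVELS["neg"], DEFAULT_SD
            redraw = vals == 0.0
            vals[redraw] = rng.normal(base_mean, base_sd, size=int(redraw.sum()))
            values[responder, j] = vals + shift
            dropout[responder, j] = False
    values += batch
    np.clip(values, 0.0, None, out=values)
    values[dropout] = 0.0  # dropout is a detection zero; the batch shift must not resurrect it

    raw = np.sinh(values) * spec.cofactor
    events = EventMatrix(
        values=raw,
        markers=list(panel.markers),
        sample_id=str(patient["patient_id"]),
        condition=condition,
        group=str(patient["group"]),
        transform="raw",
    )
    return events, labels, planted


def simulate_cohort(
    spec: CohortSpec | None = None, panel: MarkerPanel | None = None
) -> tuple[SampleSet, pd.DataFrame, GroundTruth]:
    """Simulate the full cohort (plus stimulated mates when configured)."""
    spec = spec or default_cohort_spec()
    panel = panel or default_panel()
    clin = pd.concat(
        [
            simulate_clinical(spec.n_ra, seed=spec.seed, fixture=spec.clinical_fixture),
            _healthy_rows(spec.n_healthy),
        ],
        ignore_index=True,
    )
    samples: list[EventMatrix] = []
    labels: dict[tuple[str, str], np.ndarray] = {}
    planted_rows = {}
    conditions = ["unstimulated"] + (["TLR_stimulated"] if spec.stimulated_pairs else [])
    for i, (_, patient) in enumerate(clin.iterrows()):
        sample_seed = (int(spec.seed) & 0x7FFFFFF) * 211 + i
        for condition in conditions:
            events, lab, planted = simulate_sample(
                spec, patient, condition=condition, seed=sample_seed, panel=panel
            )
            samples.append(events)
            labels[(events.sample_id, condition)] = lab
            planted_rows[events.sample_id] = planted
    truth = GroundTruth(
        labels=labels,
        planted_fractions=pd.DataFrame.from_dict(planted_rows, orient="index"),
        clinical=clin,
    )
    return SampleSet(samples=samples, panel=panel), clin, truth


def parent_label(name: str, spec: CohortSpec) -> str:
    """Map a planted subpopulation label to its parent cell type (identity otherwise)."""
    for link in spec.subpop_links:
        if link.name == name:
            return link.parent
    return name
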