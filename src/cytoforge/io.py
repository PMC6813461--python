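"""Cytometry sample I/O and preprocessing.

The central container is :class:`EventMatrix`: one sample's cells x markers
intensities plus its identity (sample id, stimulation condition, clinical
group) and transform state.  Raw ion counts are nonnegative; the standard
variance-stabilizing transform for mass cytometry is ``asinh(x / cofactor)``
with cofactor 5, applied once per sample (:func:`arcsinh_transform`).

Samples are exchanged as FCS 3.0/3.1 (see :mod:`cytoforge.fcs`) or as a
plain CSV fallback: comma-separated, UTF-8, header row of marker names, one
cell per line.  :func:`concatenate` stacks samples while keeping per-cell
provenance, and :func:`subsample_equal` draws the same number of cells from
every sample (without replacement, seeded) as required before joint
embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import fcs
from .errors import DomainError, FormatError, PanelError, StateError
from .panel import MarkerPanel

CONDITIONS = ("unstimulated", "TLR_stimulated")
GROUPS = ("RA", "healthy")


@dataclass
class EventMatrix:
    """Single-sample cells x markers expression matrix with transform state.

    ``values`` holds raw ion counts (all >= 0) when ``transform == "raw"``,
    or arcsinh-transformed intensities when ``transform == "arcsinh"`` (in
    which case ``cofactor`` records the divisor used).  ``provenance`` is an
    optional per-cell source-sample label, populated by :func:`concatenate`.
    """

    values: np.ndarray
    markers: list[str]
    sample_id: str = "sample"
    condition: str = "unstimulated"
    group: str = "healthy"
    transform: str = "raw"
    cofactor: float | None = None
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.markers = [str(m).strip() for m in self.markers]
        if self.values.ndim != 2:
            raise DomainError("values must be 2-D (cells x markers)")
        if not self.markers:
            raise DomainError("marker panel is empty")
        if self.values.shape[1] != len(self.markers):
            raise PanelError(
                f"{self.values.shape[1]} columns for {len(self.markers)} markers"
            )
        if self.values.shape[0] == 0:
            raise DomainError("sample contains no cells")
        if self.transform not in ("raw", "arcsinh"):
            raise StateError(f"unknown transform state {self.transform!r}")
        if self.transform == "raw":
            if self.cofactor is not None:
                raise StateError("raw data cannot carry a cofactor")
            if np.nanmin(self.values) < 0:
                raise DomainError("raw ion counts must be nonnegative")
        elif self.cofactor is None or self.cofactor <= 0:
            raise StateError("arcsinh data must record a positive cofactor")
        if self.condition not in CONDITIONS:
            raise DomainError(f"condition must be one of {CONDITIONS}")
        if self.group not in GROUPS:
            raise DomainError(f"group must be one of {GROUPS}")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance)
            if self.provenance.shape != (self.values.shape[0],):
                raise DomainError("provenance must have one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def marker_index(self, markers: list[str]) -> list[int]:
        pos = {m: i for i, m in enumerate(self.markers)}
        missing = [m for m in markers if m not in pos]
        if missing:
            raise PanelError(f"markers missing from sample {self.sample_id!r}: {missing}")
        return [pos[m] for m in markers]

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.marker_index([marker])[0]]


@dataclass
class SampleSet:
    """A cohort of samples sharing one panel and one transform state."""

    samples: list[EventMatrix]
    panel: MarkerPanel

    def __post_init__(self) -> None:
        if not self.samples:
            raise DomainError("empty sample set")
        ref = self.samples[0]
        for s in self.samples:
            if s.markers != self.panel.markers:
                raise PanelError(f"sample {s.sample_id!r} does not match the panel")
            if s.transform != ref.transform:
                raise StateError("samples mix transform states")
        keys = [(s.sample_id, s.condition) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise DomainError("duplicate (sample_id, condition) pairs in sample set")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def get(self, sample_id: str, condition: str = "unstimulated") -> EventMatrix:
        for s in self.samples:
            if s.sample_id == sample_id and s.condition == condition:
                return s
        raise KeyError((sample_id, condition))


def _infer_format(path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = Path(path).suffix.lower()
    return "fcs" if suffix == ".fcs" else "csv"


def read_sample(
    path,
    format: str | None = None,
    panel: MarkerPanel | None = None,
    sample_id: str | None = None,
    condition: str = "unstimulated",
    group: str = "healthy",
) -> EventMatrix:
    """Read one raw sample from FCS or CSV.

    Marker names come from FCS ``$PnS`` falling back to ``$PnN``, or the CSV
    header.  If *panel* is given the file's markers must match it exactly
    (after whitespace trimming); a mismatch raises :class:`PanelError`
    listing the missing markers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "fcs":
        values, names, _ = fcs.read_fcs(path)
    elif fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] == 0:
            raise FormatError(f"{path}: CSV has no columns")
        names = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=np.float64)
    else:
        raise DomainError(f"unknown format {fmt!r}")
    names = [n.strip() for n in names]
    if panel is not None:
        missing = [m for m in panel.markers if m not in names]
        if missing:
            raise PanelError(f"{path}: markers missing from file: {missing}")
        order = [names.index(m) for m in panel.markers]
        values = values[:, order]
        names = list(panel.markers)
    return EventMatrix(
        values=values,
        markers=names,
        sample_id=sample_id or path.stem,
        condition=condition,
        group=group,
    )


def write_sample(m: EventMatrix, path, format: str | None = None) -> Path:
    """Write a sample to FCS (3.1, float32) or CSV; returns the path written."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "fcs":
        fcs.write_fcs(path, m.values, m.markers)
    elif fmt == "csv":
        pd.DataFrame(m.values, columns=m.markers).to_csv(path, index=False)
    else:
        raise DomainError(f"unknown format {fmt!r}")
    return path


def arcsinh_transform(m: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """Apply ``asinh(x / cofactor)`` to a raw sample."""
    if cofactor <= 0:
        raise DomainError(f"cofactor must be positive, got {cofactor}")
    if m.transform != "raw":
        raise StateError(f"sample {m.sample_id!r} is already transformed")
    return replace(
        m,
        values=np.arcsinh(m.values / cofactor),
        transform="arcsinh",
        cofactor=float(cofactor),
    )


def concatenate(samples: list[EventMatrix]) -> EventMatrix:
    """Row-stack samples, recording per-cell provenance (source sample_id)."""
    if not samples:
        raise DomainError("nothing to concatenate")
    ref = samples[0]
    for s in samples:
        if s.markers != ref.markers:
            raise PanelError("samples do not share a marker panel")
        if s.transform != ref.transform or s.cofactor != ref.cofactor:
            raise StateError("samples mix transform states")
    values = np.vstack([s.values for s in samples])
    provenance = np.concatenate(
        [
            s.provenance if s.provenance is not None else np.full(s.n_cells, s.sample_id, dtype=object)
            for s in samples
        ]
    )
    conditions = {s.condition for s in samples}
    groups = {s.group for s in samples}
    return EventMatrix(
        values=values,
        markers=list(ref.markers),
        sample_id="+".join(dict.fromkeys(s.sample_id for s in samples)),
        condition=conditions.pop() if len(conditions) == 1 else "unstimulated",
        group=groups.pop() if len(groups) == 1 else "healthy",
        transform=ref.transform,
        cofactor=ref.cofactor,
        provenance=provenance,
    )


def subsample_equal(
    samples: list[EventMatrix], n_per_sample: int, seed: int
) -> list[EventMatrix]:
    """Draw the same number of cells from each sample, without replacement.

    ``n_per_sample`` is clamped to the smallest sample so every output has
    an identical cell count.  Selection is reproducible under *seed* and
    independent per sample.
    """
    if n_per_sample <= 0:
        raise DomainError(f"n_per_sample must be positive, got {n_per_sample}")
    if not samples:
        return []
    n = min(n_per_sample, min(s.n_cells for s in samples))
    out = []
    for i, s in enumerate(samples):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, i])
        idx = np.sort(rng.choice(s.n_cells, size=n, replace=False))
        out.append(
            replace(
                s,
                values=s.values[idx],
                provenance=None if s.provenance is None else s.provenance[idx],
            )
        )
    return out
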