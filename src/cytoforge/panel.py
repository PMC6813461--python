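"""Marker panel definition for the 33-marker leukocyte CyTOF panel.

A :class:`MarkerPanel` records the ordered marker names, their metal tags,
whether each is stained extra- or intracellularly, and named marker subsets
used by the different analysis arms:

``all33``
    every marker; used for the main 500-cluster SPADE run.
``stim20``
    the 20 surface/effector markers used to re-cluster the TLR-stimulation
    arm (CD3, CD11a, CD11b, CD11c, CD14, CD16, CD19, CD23, CD28, CD32, CD64,
    CD66, CD86, CD123, CCR5, CXCR4, Granzyme B, Perforin, TLR2, HLADR).
``annotation9`` / ``annotation9_stim``
    the marker sets used to annotate clusters to cell types; the stimulation
    arm swaps Granzyme B for CD64.
``cytokines``
    the intracellular cytokines scored after stimulation.

The published 33-marker list lives in a supplement that is not distributed
with this package; the default panel carries the 23 markers the study names
explicitly plus ten fillers (six generic leukocyte markers and four
placeholders) so that panel-sized data can be generated and round-tripped.
Panels for real data should be loaded from a YAML file via
:func:`load_panel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import PanelError

STIM20 = [
    "CD3", "CD11a", "CD11b", "CD11c", "CD14", "CD16", "CD19", "CD23",
    "CD28", "CD32", "CD64", "CD66", "CD86", "CD123", "CCR5", "CXCR4",
    "GranzymeB", "Perforin", "TLR2", "HLADR",
]
ANNOTATION9 = ["CD3", "CD11c", "CD14", "CD16", "CD19", "CD66", "CD123", "GranzymeB", "HLADR"]
ANNOTATION9_STIM = ["CD3", "CD11c", "CD14", "CD16", "CD19", "CD64", "CD66", "CD123", "HLADR"]
CYTOKINES = ["MIP-1b", "TNF-a", "IL-8"]

_FILLERS = ["CD45", "CD38", "CD62L", "CD69", "IL-6", "IL-1a"]
# Panel positions whose identity is not recoverable from the study text.
_PLACEHOLDERS = ["Marker-30", "Marker-31", "Marker-32", "Marker-33"]

_INTRACELLULAR = {"GranzymeB", "Perforin", "MIP-1b", "TNF-a", "IL-8", "IL-6", "IL-1a"}

_METALS = [
    "Y89", "In113", "In115", "La139", "Pr141", "Nd142", "Nd143", "Nd144",
    "Nd145", "Nd146", "Sm147", "Nd148", "Sm149", "Nd150", "Eu151", "Sm152",
    "Eu153", "Sm154", "Gd155", "Gd156", "Gd158", "Tb159", "Gd160", "Dy161",
    "Dy162", "Dy163", "Dy164", "Ho165", "Er166", "Er167", "Er168", "Tm169",
    "Er170",
]


@dataclass
class MarkerPanel:
    """Ordered marker panel with metal tags, stain classes and named subsets."""

    markers: list[str]
    metal_tag: dict[str, str] = field(default_factory=dict)
    stain_class: dict[str, str] = field(default_factory=dict)
    clustering_set: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = [m.strip() for m in self.markers]
        if len(set(self.markers)) != len(self.markers):
            raise PanelError("duplicate marker names in panel")
        known = set(self.markers)
        for name, subset in self.clustering_set.items():
            missing = [m for m in subset if m not in known]
            if missing:
                raise PanelError(f"clustering set {name!r} references unknown markers: {missing}")
        for m, cls in self.stain_class.items():
            if cls not in ("extracellular", "intracellular"):
                raise PanelError(f"invalid stain class {cls!r} for marker {m!r}")

    def __len__(self) -> int:
        return len(self.markers)

    def subset(self, name: str) -> list[str]:
        """Return a named clustering set, validating it exists."""
        try:
            return list(self.clustering_set[name])
        except KeyError:
            raise PanelError(f"unknown clustering set {name!r}; have {sorted(self.clustering_set)}") from None

    def index(self, markers: list[str]) -> list[int]:
        """Column indices of the given markers in panel order."""
        pos = {m: i for i, m in enumerate(self.markers)}
        missing = [m for m in markers if m not in pos]
        if missing:
            raise PanelError(f"markers not in panel: {missing}")
        return [pos[m] for m in markers]


def default_panel() -> MarkerPanel:
    """The default 33-marker panel (23 named study markers + 10 fillers)."""
    markers = STIM20 + CYTOKINES + _FILLERS + _PLACEHOLDERS
    assert len(markers) == 33
    return MarkerPanel(
        markers=markers,
        metal_tag=dict(zip(markers, _METALS)),
        stain_class={m: ("intracellular" if m in _INTRACELLULAR else "extracellular") for m in markers},
        clustering_set={
            "all33": list(markers),
            "stim20": list(STIM20),
            "annotation9": list(ANNOTATION9),
            "annotation9_stim": list(ANNOTATION9_STIM),
            "cytokines": list(CYTOKINES),
        },
    )


def load_panel(path) -> MarkerPanel:
    """Load a panel from a YAML file with keys markers/metal_tag/stain_class/clustering_set."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not cfg or "markers" not in cfg or not cfg["markers"]:
        raise PanelError(f"panel file {path} lists no markers")
    return MarkerPanel(
        markers=list(cfg["markers"]),
        metal_tag=dict(cfg.get("metal_tag", {})),
        stain_class=dict(cfg.get("stain_class", {})),
        clustering_set={k: list(v) for k, v in cfg.get("clustering_set", {}).items()},
    )


def save_panel(panel: MarkerPanel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "markers": panel.markers,
                "metal_tag": panel.metal_tag,
                "stain_class": panel.stain_class,
                "clustering_set": panel.clustering_set,
            },
            fh,
            sort_keys=False,
        )
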