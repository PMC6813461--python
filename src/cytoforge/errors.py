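"""Exception hierarchy.

Every error raised by this package derives from :class:`CytoforgeError`, so
callers can catch one type at a pipeline boundary.  The subclasses map to the
failure modes of cytometry work: malformed files, panel mismatches,
transform-state misuse, out-of-domain parameters, and bad analysis
definitions (annotation rules, gating areas, stage dependencies).
"""


class CytoforgeError(Exception):
    """Base class for all package errors."""


class FormatError(CytoforgeError):
    """A file does not conform to its declared format (names the offending keyword)."""


class PanelError(CytoforgeError):
    """Marker names do not match the supplied panel."""


class StateError(CytoforgeError):
    """An operation was applied in the wrong transform state (e.g. double arcsinh)."""


class DomainError(CytoforgeError, ValueError):
    """A numeric parameter is outside its valid domain."""


class SpecError(CytoforgeError):
    """A simulation spec references unknown populations or covariates."""


class RuleError(CytoforgeError):
    """An annotation rule is self-contradictory or references unknown markers."""


class AreaError(CytoforgeError):
    """Gating-area definitions overlap or are otherwise invalid."""


class SelectionError(CytoforgeError):
    """A selection (cell-type isolation, thresholding) matched nothing usable."""


class InputError(CytoforgeError):
    """Mismatched or missing analysis inputs (lengths, group labels, markers)."""


class DependencyError(CytoforgeError):
    """A pipeline stage was requested before its prerequisite stage produced output."""
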