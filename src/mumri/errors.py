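"""Exception hierarchy.

Two families: hard errors (malformed or inconsistent inputs) and "signals" —
expected analysis outcomes such as a profile with no inflection or a region
that never alternates.  Signals subclass :class:`AnalysisSignal` so pipeline
code can catch them collectively without masking real errors.
"""


class MumriError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MumriError):
    """A file does not conform to the expected on-disk format."""


class ConsistencyError(MumriError):
    """Inputs are individually valid but mutually inconsistent."""


class GeometryError(MumriError):
    """A requested shape does not fit the voxel grid."""


class AnalysisSignal(MumriError):
    """An expected negative analysis outcome (not a malfunction)."""


class NoInflectionError(AnalysisSignal):
    """Current-intensity profile shows no significant slope change."""


class NoAlternationError(AnalysisSignal):
    """Region intensity trace is not separable into void / no-void states."""


class NoActivityError(AnalysisSignal):
    """Difference map has no positive signal to normalise."""


class DegenerateInputError(MumriError):
    """A statistic is undefined for this input (e.g. zero variance)."""


class ParameterWarning(UserWarning):
    """A parameter is outside its usual operating range but still usable."""
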