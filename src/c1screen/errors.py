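"""Exception hierarchy for the c1screen pipeline."""


class C1ScreenError(Exception):
    """Base class for all package errors."""


class GroParseError(C1ScreenError):
    """Malformed GRO input; message names the offending frame/line."""


class GroWriteError(C1ScreenError):
    """Trajectory cannot be represented in GRO fixed columns."""


class UnsupportedFormatError(C1ScreenError):
    """Valid file, but a dialect the pipeline does not support (e.g. triclinic box)."""


class SelectionError(C1ScreenError):
    """Invalid index group or ligand atom-group specification."""


class GeometryError(C1ScreenError):
    """Degenerate geometry: disconnected bond graph, zero-length axis, empty group."""


class AnalysisError(C1ScreenError):
    """An observable is undefined on this input (no mode, no interface crossing, ...)."""


class ConfigError(C1ScreenError):
    """Inconsistent thresholds, cutoffs or scenario configuration."""
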