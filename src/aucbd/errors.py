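"""Exception hierarchy shared by all aucbd modules."""


class DomainError(ValueError):
    """A physical quantity is outside its admissible domain (e.g. rpm <= 0)."""


class FlotationError(DomainError):
    """The species would float (vbar * rho >= 1); outward sedimentation only."""


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration (settings, windows, counts, ...)."""


class AlignmentError(ValueError):
    """Two scan sets do not share the same radius/time grid."""


class AnalysisError(RuntimeError):
    """A data-analysis step could not produce a result (e.g. no plateau)."""


class NumericalError(RuntimeError):
    """Non-finite values appeared where finite numbers are required."""


class ConsistencyError(RuntimeError):
    """An internal invariant was violated (e.g. particle count not conserved)."""


class ScanParseError(ValueError):
    """A scan file could not be parsed; carries file and line context."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
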