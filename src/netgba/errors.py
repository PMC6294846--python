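"""Exception hierarchy for the pipeline stages."""


class NetGBAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NetGBAError):
    """Invalid simulation or pipeline configuration."""


class DesignError(NetGBAError):
    """Invalid sample design (groups, labels, matrix shape)."""


class EstimationError(NetGBAError):
    """A statistical estimate cannot be formed (e.g. no variance anywhere)."""


class NetworkError(NetGBAError):
    """Co-expression network cannot be built."""


class AnnotationError(NetGBAError):
    """Annotation data is unusable (empty intersection, nothing survives a filter)."""


class ParseError(NetGBAError):
    """A malformed line in an input file; carries the line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


class EvaluationError(NetGBAError):
    """Cross-validated evaluation cannot proceed."""
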