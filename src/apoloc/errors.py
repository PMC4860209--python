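"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`ApolocError`, so callers (and the CLI) can catch one type.
"""


class ApolocError(Exception):
    """Base class for all apoloc errors."""


class OntologyError(ApolocError):
    """The ontology is unusable (no terms, no cellular-component terms, ...)."""


class ParseError(ApolocError):
    """A file violated its format contract.

    Carries the 1-based line number when it is known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(ApolocError):
    """Inputs are well-formed but inconsistent (duplicate labels, null vectors, ...)."""


class ParameterError(ApolocError):
    """A numeric parameter is out of its admissible range (e.g. K > training size)."""


class DimensionError(ApolocError):
    """Feature vectors of mismatched length were combined."""


class UndefinedMetricError(ApolocError):
    """A per-class metric was requested for a class with no positives/negatives."""


class ConfigError(ApolocError):
    """A simulation or run configuration is invalid."""
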