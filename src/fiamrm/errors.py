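"""Exception hierarchy shared across the package."""


class FiamrmError(Exception):
    """Base class for all package errors."""


class InputError(FiamrmError, ValueError):
    """Malformed user input (identifiers, tables, parameters)."""


class FetchError(FiamrmError):
    """Transport-level failure while resolving identifiers.

    Distinct from an identifier that resolves to "absent": a FetchError is
    retryable, an absent link is a final answer.
    """


class SpectrumParseError(FiamrmError, ValueError):
    """A predicted-spectrum document could not be parsed."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class UndefinedMetricError(FiamrmError, ValueError):
    """Spectrum comparison metrics are undefined (empty peak list)."""


class MetaboliteExcluded(FiamrmError):
    """A metabolite cannot be carried forward (e.g. no pKa -> no ESI mode)."""


class PipelineOrderError(FiamrmError, RuntimeError):
    """QC/statistics steps invoked out of their mandatory order."""
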