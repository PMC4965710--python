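"""Exception hierarchy.

All package errors derive from :class:`EhrWeightsError` so callers can catch
broadly; most are also ``ValueError`` subclasses for scikit-learn interop.
"""


class EhrWeightsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EhrWeightsError, ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(EhrWeightsError, ValueError):
    """Parsed content violates a domain invariant."""


class ConfigurationError(EhrWeightsError, ValueError):
    """A simulation or run configuration violates its invariants."""


class DegenerateWeightsError(EhrWeightsError, ValueError):
    """All feature weights are zero; no sampling distribution exists."""


class StratificationError(EhrWeightsError, ValueError):
    """A class is too small for the requested stratified fold plan."""


class CoverageError(EhrWeightsError, KeyError):
    """A weight table does not address every feature column."""

    def __init__(self, missing):
        self.missing = list(missing)
        preview = ", ".join(map(str, self.missing[:5]))
        more = "" if len(self.missing) <= 5 else f" (+{len(self.missing) - 5} more)"
        super().__init__(f"weights missing for columns: {preview}{more}")
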