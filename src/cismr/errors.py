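"""Exception hierarchy.

Configuration problems (bad column mappings, schema violations) are kept
distinct from data problems (invalid values, empty results) so callers can
decide what is retryable.
"""


class CismrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CismrError):
    """A config file, dialect, or argument combination is invalid."""


class DataError(CismrError):
    """Input data violates an invariant (bad values, empty result, asymmetry)."""


class NoInstrumentsError(DataError):
    """Every candidate SNP was removed by the filter chain or harmonization.

    ``filter_name`` names the first step that emptied the set.
    """

    def __init__(self, message: str, filter_name: str | None = None):
        super().__init__(message)
        self.filter_name = filter_name
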