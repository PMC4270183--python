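"""Exception hierarchy shared across the package."""


class NicheGRNError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NicheGRNError, ValueError):
    """A file or record did not match the expected format."""


class DegenerateDistributionError(NicheGRNError, ValueError):
    """Too few distinct values (or zero spread) to discretize or standardize."""


class ContextualizationError(NicheGRNError, RuntimeError):
    """No admissible network satisfies the requested consistency constraint.

    Carries the best report found so far in ``report`` when available.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
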