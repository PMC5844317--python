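"""Exception types raised across the pipeline."""


class BalancerScanError(Exception):
    """Base class for package errors."""


class FormatError(BalancerScanError):
    """A file violates its declared format (missing field, bad record)."""


class CohortError(BalancerScanError):
    """Cohort-level inconsistency (e.g. duplicate strain identifiers)."""


class IntervalError(BalancerScanError):
    """A genomic interval is malformed."""


class SizingError(BalancerScanError):
    """A simulation request cannot be packed into the given genome size."""


class ConfigurationError(BalancerScanError):
    """Inputs are mutually inconsistent (e.g. zones do not match genes)."""


class DegenerateInputError(BalancerScanError):
    """A statistic was requested on an input with no information (all zeros)."""
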