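"""Exception hierarchy shared by all pankit modules."""


class PankitError(Exception):
    """Base class for all pankit errors."""


class FormatError(PankitError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(PankitError):
    """Well-formed input violates a domain invariant."""


class ConfigError(PankitError):
    """A configuration value is out of range or infeasible."""


class IntegrityError(PankitError):
    """Cross-object references are inconsistent (unknown ids, unsorted input)."""


class FitError(PankitError):
    """A model fit is degenerate and cannot be performed."""
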