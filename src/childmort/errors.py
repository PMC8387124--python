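"""Exception taxonomy shared across the pipeline."""


class ChildmortError(Exception):
    """Base class for package errors."""


class FormatError(ChildmortError):
    """Input file does not match the expected layout."""


class ValidationError(ChildmortError):
    """Input values violate an invariant (e.g. negative deaths)."""


class EligibilityError(ChildmortError):
    """A country-year fails the inclusion criteria (infant deaths not
    split into the four sub-year categories)."""


class AggregationError(ChildmortError):
    """Pooling failed: missing population record, zero exposure, empty
    selection."""


class InsufficientDataError(ChildmortError):
    """Too few usable points for the requested fit or test."""


class ConfigError(ChildmortError):
    """Run configuration is inconsistent or incomplete."""
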