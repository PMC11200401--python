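"""Exception hierarchy shared by all flysin modules."""


class FlysinError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FlysinError):
    """A parameter, criteria set, or config field is invalid or unknown."""


class ValidationError(FlysinError):
    """Input data violates a structural invariant (duplicates, bad ids...)."""


class DialectError(ConfigurationError):
    """Unknown trajectory-table dialect."""
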