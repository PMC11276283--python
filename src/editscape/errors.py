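"""Exception hierarchy."""


class EditscapeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EditscapeError):
    """A configuration value is invalid; the message names the field."""


class ContractViolationError(EditscapeError):
    """A caller violated a documented precondition."""


class ParseError(EditscapeError):
    """A text input could not be parsed; the message carries the line number."""


class ValidationError(EditscapeError):
    """Parsed input violates a semantic invariant (e.g. duplicate locus)."""


class InsufficientDataError(EditscapeError):
    """Too few usable observations for the requested statistic."""


class EmptyInputError(EditscapeError):
    """A selection step left nothing to operate on."""


class FixtureError(EditscapeError):
    """A constructed-read specification is inconsistent with the site catalog."""
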