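"""Exception types."""


class GermscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GermscreenError):
    """A configuration file is missing required structure."""


class ValidationError(GermscreenError):
    """Input data violates a documented invariant."""


class ParseError(GermscreenError):
    """A record could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class OffPanelError(GermscreenError):
    """A gene symbol is not part of the configured panel."""
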