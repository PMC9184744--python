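"""Exception hierarchy shared across the toolkit."""


class MPSKitError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(MPSKitError, ValueError):
    """A simulation or run configuration field is invalid; the message names the field."""


class FormatError(MPSKitError, ValueError):
    """An input file does not match the declared schema."""


class AnalysisError(MPSKitError, ValueError):
    """An analysis operation received data it cannot process (too short, empty, mismatched)."""
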