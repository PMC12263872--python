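"""Exception types shared across the toolkit."""


class SwarmSpeechError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(SwarmSpeechError, ValueError):
    """Raised when runtime data (signals, labels, tables) violates a precondition."""


class ConfigurationError(SwarmSpeechError, ValueError):
    """Raised when a configuration object is internally inconsistent."""
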