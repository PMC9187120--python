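"""Exception hierarchy shared across the package."""


class SpikesightError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpikesightError):
    """A session directory or table is missing or malformed."""


class ValidationError(SpikesightError):
    """A record violates a domain invariant; the message names the record."""


class ConfigError(SpikesightError):
    """A simulation or pipeline configuration value is invalid."""


class AnalysisError(SpikesightError):
    """An analysis cannot be carried out on the given input.

    Raised, e.g., when a waveform never returns to baseline, when no trial
    passes an outcome filter, or when a test has an empty group.
    """
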