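"""Exception hierarchy for peakrate."""


class PeakrateError(Exception):
    """Base class for all peakrate errors."""


class FormatError(PeakrateError):
    """A peak-table file could not be parsed (missing column, empty file, ...)."""


class ValidationError(PeakrateError):
    """An in-memory object violates a structural invariant."""


class ConfigError(PeakrateError):
    """A configuration value is invalid or internally inconsistent."""
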