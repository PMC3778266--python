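"""Exception hierarchy shared across the package."""


class RoiconcordError(Exception):
    """Base class for all package errors."""


class ConfigError(RoiconcordError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DataError(RoiconcordError, ValueError):
    """Invalid or inconsistent input data (empty groups, missing columns, NaN)."""


class MappingError(DataError):
    """ROI map and measurement table disagree (missing sub-ROI or area columns)."""


class DegenerateInputError(DataError):
    """Mathematically degenerate input (zero total area, empty reduction)."""
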