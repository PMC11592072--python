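"""Exception hierarchy.

Everything raised on bad user input derives from :class:`MetaboplsError`
so callers can catch one type at a pipeline boundary.
"""


class MetaboplsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MetaboplsError, ValueError):
    """An invalid configuration value; the message names the field."""


class PeakTableError(MetaboplsError, ValueError):
    """Malformed peak table (duplicate ids, negative intensities, ...)."""


class MetadataError(MetaboplsError, ValueError):
    """Malformed sample metadata."""


class PreprocessError(MetaboplsError, ValueError):
    """A preprocessing step cannot be applied (too few QCs, missing values, ...)."""


class ModelError(MetaboplsError, ValueError):
    """A model cannot be fitted or applied as requested."""
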