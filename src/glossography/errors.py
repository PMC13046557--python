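"""Exception hierarchy.

The CLI maps these onto exit codes: usage/config problems exit 2,
data-quality problems exit 3.
"""


class GlossographyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GlossographyError):
    """A landmark table does not conform to the expected dialect."""


class DataQualityError(GlossographyError):
    """The data are parseable but unusable (e.g. a confidence gap too long)."""


class ConfigError(GlossographyError):
    """An analysis configuration is invalid or contains unknown keys."""
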