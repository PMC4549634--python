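"""Exception hierarchy.

Configuration problems (bad flags, bad column maps) and data problems
(misaligned rasters, invalid counts) are kept distinct so the command-line
layer can map them onto different exit codes.
"""


class IgnomapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IgnomapError):
    """Invalid user configuration: bad parameter, missing column, bad flag."""


class ValidationError(IgnomapError):
    """Input data violates a contract (e.g. richness exceeding counts)."""


class AlignmentError(ValidationError):
    """Two gridded layers do not share the exact same extent/resolution/CRS."""


class DegenerateEffortError(ValidationError):
    """Effort layer has no positive cell, so max-normalizing formulas are undefined."""
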