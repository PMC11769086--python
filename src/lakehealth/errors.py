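"""Exception hierarchy shared across the package."""


class LakeHealthError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LakeHealthError):
    """A file could not be parsed into the expected tabular layout."""


class ValidationError(LakeHealthError):
    """Parsed data violates a domain invariant (signs, duplicates, coverage)."""


class ConfigError(LakeHealthError):
    """A configuration value is outside its admissible range."""


class ParameterError(LakeHealthError):
    """A function argument is outside its admissible range."""


class ModelBuildError(LakeHealthError):
    """The O/E model cannot be built from the supplied reference data."""


class UndefinedScoreError(LakeHealthError):
    """A score is undefined for a site (e.g. expected richness of zero)."""
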