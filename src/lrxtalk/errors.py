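"""Typed exceptions used across the package."""


class LrxtalkError(Exception):
    """Base class for all package errors."""


class FormatError(LrxtalkError):
    """A file or table failed structural validation."""


class ConfigError(LrxtalkError):
    """A configuration value is invalid or inconsistent."""


class ConstantInputError(LrxtalkError):
    """A statistic is undefined because an input vector is constant."""
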