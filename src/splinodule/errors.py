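"""Exception hierarchy shared across the package.

The CLI maps :class:`ConfigurationError` to exit code 2 and
:class:`FormatError` / :class:`GenerationError` to exit code 3.
"""


class SplinoduleError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SplinoduleError):
    """Invalid parameters, unsupported family/order combinations, bank mismatches."""


class FormatError(SplinoduleError):
    """Unreadable or unsupported image / container / config data."""


class GenerationError(SplinoduleError):
    """Phantom synthesis failed (e.g. structure placement exhausted its attempts)."""
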