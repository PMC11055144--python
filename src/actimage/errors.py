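"""Exception hierarchy shared across the package."""


class ActimageError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ActimageError, ValueError):
    """A file does not conform to the documented interchange schema."""


class SamplingError(ActimageError, ValueError):
    """Time axis of a motion table is non-uniform or inconsistent."""


class ValidationError(ActimageError, ValueError):
    """An in-memory object violates its contract."""


class ConfigurationError(ActimageError, ValueError):
    """A parameter or joint-name configuration is invalid."""
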