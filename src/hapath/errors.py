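"""Exception types shared across the package."""


class HapathError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(HapathError, ValueError):
    """A configuration object or file is invalid; message names the field."""


class SchemaError(HapathError, ValueError):
    """A table is missing mandatory columns or has an unparseable column."""


class DegenerateDataError(HapathError, ValueError):
    """Input data cannot support the requested computation (e.g. constant
    indicator, zero outcome variance)."""


class IntegrityError(HapathError, ValueError):
    """Internally inconsistent inputs (mismatched draw lengths, unpaired
    rows)."""
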