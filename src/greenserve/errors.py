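"""Exception hierarchy shared across the pipeline."""


class GreenserveError(Exception):
    """Base class for all package errors."""


class ConfigError(GreenserveError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(GreenserveError):
    """Invalid, unreadable or inconsistent data (CLI exit code 3)."""
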