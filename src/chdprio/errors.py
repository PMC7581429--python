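"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (config error -> 2, data error -> 3,
stage failure -> 4).
"""


class ChdprioError(Exception):
    """Base class for all package errors."""


class ConfigError(ChdprioError):
    """Invalid configuration or parameter value."""


class DataError(ChdprioError):
    """Malformed, missing or inconsistent input data."""


class StageError(ChdprioError):
    """A pipeline stage failed on otherwise well-formed input."""
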