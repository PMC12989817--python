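"""Exception hierarchy shared across the pipeline.

Exit-code convention for the CLI: 0 ok, 1 data/format error, 2
configuration error.
"""


class TurbomapError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigError(TurbomapError):
    """Invalid parameters, fractions, group names or pipeline config."""

    exit_code = 2


class DataError(TurbomapError):
    """Input values violate a contract (negative intensity, missing bait, ...)."""

    exit_code = 1


class FormatError(DataError):
    """A file does not conform to its expected dialect."""

    exit_code = 1
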