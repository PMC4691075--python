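"""Exception hierarchy shared across the pipeline.

Exit-code contract for the command line: 0 success, 2 input/format
problems, 3 internal consistency violations.
"""


class HopperPathError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class FormatError(HopperPathError):
    """A file or value does not follow the documented dialect."""

    exit_code = 2


class ConfigError(HopperPathError):
    """An invalid pipeline or simulation configuration."""

    exit_code = 2


class DomainError(HopperPathError):
    """A value outside the mathematical domain of an operation."""

    exit_code = 2


class ConsistencyError(HopperPathError):
    """Inputs that are individually well-formed but mutually contradictory."""

    exit_code = 3
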