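"""Typed errors with CLI exit codes."""


class MirenrichError(Exception):
    """Base error for the package; carries the CLI exit status."""

    exit_code = 1


class InputError(MirenrichError):
    """Malformed or missing input data (exit 2)."""

    exit_code = 2


class ConfigError(MirenrichError):
    """Invalid configuration (exit 3)."""

    exit_code = 3


class EmptyResultError(MirenrichError):
    """A step produced no usable output, e.g. zero testable families (exit 4)."""

    exit_code = 4
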