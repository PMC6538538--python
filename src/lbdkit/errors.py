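"""Exception hierarchy shared across the pipeline.

Each error class carries the process exit code the command-line layer maps
it to, so library callers and shell callers see consistent failure classes.
"""


class LbdError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigError(LbdError):
    """Invalid or inconsistent run configuration."""

    exit_code = 2


class DataError(LbdError):
    """Malformed, missing, or semantically invalid input data."""

    exit_code = 3


class ResourceLimitError(LbdError):
    """A computation would exceed its declared memory budget.

    Raised *before* allocation so the caller can fall back (e.g. to the
    isolation forest, whose memory footprint is bounded by the subsample
    size) instead of crashing the process.
    """

    exit_code = 4


class DegenerateInputError(DataError):
    """Input is technically parseable but statistically degenerate
    (e.g. zero-variance training data, all-identical paired samples)."""
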