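"""Exception hierarchy.

All package errors derive from :class:`DeregError` so callers (and the CLI)
can map failure classes to exit codes.
"""


class DeregError(Exception):
    """Base class for all errors raised by this package."""


class DataError(DeregError):
    """Malformed or inconsistent input data (files, matrices, networks)."""


class GraphError(DeregError):
    """Factor-graph construction or inference failure (e.g. contradictory
    hard constraints yielding an all-zero belief, or an enumeration request
    whose state space exceeds the configured cap)."""


class FitError(DeregError):
    """EM fitting failure (degenerate input, unrecoverable M-step state)."""
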