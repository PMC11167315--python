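"""Exception hierarchy.

``UsageError`` marks caller mistakes (mismatched documents, bad
parameters); ``ConfigError`` and ``ReadError`` mark malformed inputs on
disk; ``GenerationError`` marks infeasible synthetic-corpus requests.
"""


class DeidevalError(Exception):
    """Base class for all package-specific errors."""


class UsageError(DeidevalError):
    """The caller violated a precondition (not a data problem)."""


class ConfigError(DeidevalError):
    """A schema configuration file is malformed or inconsistent."""


class ReadError(DeidevalError):
    """An annotation file could not be parsed or failed validation."""


class GenerationError(DeidevalError):
    """Synthetic corpus parameters are infeasible (e.g. spans cannot fit)."""
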