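"""Exception hierarchy.

Input problems (malformed tables, bad ids), configuration problems
(out-of-range thresholds) and numerical problems (degenerate data) are
distinguished so the command line can map them to distinct exit codes.
"""


class ComiraError(Exception):
    """Base class for all package errors."""


class InputError(ComiraError, ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ComiraError, ValueError):
    """Invalid analysis configuration."""


class NumericalError(ComiraError, ValueError):
    """Degenerate data that makes a statistic undefined."""
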