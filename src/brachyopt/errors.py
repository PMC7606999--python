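"""Error hierarchy with stable categories for scripted pipelines.

Each category maps to a distinct nonzero exit code in the CLI so that
callers can distinguish bad user input from corrupt configuration data
and from plans that are mathematically degenerate (e.g. zero dose
everywhere, making D90% normalization impossible).
"""


class BrachyoptError(Exception):
    """Base class; ``category`` drives the CLI exit code."""

    category = "internal"
    exit_code = 1


class InputError(BrachyoptError):
    """Invalid or inconsistent user-supplied inputs (shapes, paths, values)."""

    category = "input"
    exit_code = 2


class ConfigurationError(BrachyoptError):
    """Invalid source/phantom/objective configuration data."""

    category = "config"
    exit_code = 3


class DegeneratePlanError(BrachyoptError):
    """A plan on which the requested operation is mathematically undefined."""

    category = "degenerate-plan"
    exit_code = 4
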