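"""Exception hierarchy.

Error codes are stable strings so that CLI callers and the pipeline can
distinguish user errors (bad files, bad values) from internal failures
(solver breakdown) without parsing messages.
"""


class InflammodeError(Exception):
    """Base class for all package errors."""

    code = "internal"


class InvalidInputError(InflammodeError, ValueError):
    """A caller-supplied value violates a documented precondition."""

    code = "invalid-input"


class SchemaError(InvalidInputError):
    """A parameter/config file does not match the expected schema."""

    code = "schema"


class UnknownParameterError(SchemaError):
    """A parameter name is not part of the model vocabulary."""

    code = "unknown-parameter"


class MissingParameterError(SchemaError):
    """A required parameter name is absent from a file."""

    code = "missing-parameter"


class PositivityError(SchemaError):
    """A parameter value violates the positivity/Hill constraints."""

    code = "positivity"


class SimulationError(InflammodeError, RuntimeError):
    """The ODE solver failed; carries solver diagnostics."""

    code = "simulation"

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConvergenceError(InflammodeError, RuntimeError):
    """An iterative routine (root finder, optimizer) did not converge."""

    code = "convergence"
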