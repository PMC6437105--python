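"""Exception hierarchy shared across the package."""


class PhagecharError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PhagecharError, ValueError):
    """A parameter violates a precondition (non-positive titer, bad dilution, ...)."""


class EstimationError(PhagecharError):
    """An estimator cannot produce a result from the given data."""


class UndefinedMOIError(InvalidParameterError):
    """MOI requested with zero bacterial count."""


class InvalidReferenceError(InvalidParameterError):
    """A reference titer (host PFU, initial count) is missing or non-positive."""


class SchemaError(PhagecharError):
    """A table or config does not match the expected schema.

    Carries enough location detail (file, row, column) to fix the input.
    """

    def __init__(self, message, *, path=None, row=None, column=None):
        loc = []
        if path is not None:
            loc.append(f"file={path}")
        if row is not None:
            loc.append(f"row={row}")
        if column is not None:
            loc.append(f"column={column}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.path, self.row, self.column = path, row, column


class ScenarioError(PhagecharError, KeyError):
    """Unknown scenario name or invalid scenario composition."""


class IntegrationError(PhagecharError):
    """The ODE integrator failed; message names the scenario and failing time."""
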