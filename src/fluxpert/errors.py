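"""Exception hierarchy.

``InputError`` maps to CLI exit code 2, ``InfeasibleModelError`` to 3.
"""


class FluxpertError(Exception):
    """Base class for all package errors."""


class InputError(FluxpertError):
    """Malformed or inconsistent user input (files, ids, bounds)."""


class InfeasibleModelError(FluxpertError):
    """An LP that must be solvable is infeasible or unbounded."""

    def __init__(self, message: str, status: str = "infeasible"):
        super().__init__(message)
        self.status = status
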