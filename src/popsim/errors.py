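"""Exception hierarchy shared across the package."""


class PopsimError(Exception):
    """Base class for all popsim errors."""


class ValidationError(PopsimError):
    """An object violates one of its invariants.

    ``field`` names the offending field so callers (and tests) can pin
    down which invariant fired.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class UnsupportedVersionError(PopsimError):
    """A serialized file declares a schema version newer than this build."""


class ParseError(PopsimError):
    """Malformed input file; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


class IntegrityError(PopsimError):
    """A results bundle failed its checksum verification."""


class AssemblyError(PopsimError):
    """A model selection cannot be turned into an ODE system."""


class ContractError(PopsimError):
    """A user callback violated its calling contract."""


class StepBudgetError(PopsimError):
    """The integrator exceeded its internal step budget."""

    def __init__(self, t: float, budget: int):
        self.t = t
        self.budget = budget
        super().__init__(
            f"integration exceeded the budget of {budget} internal steps near t={t:g} h"
        )


class DivergenceError(PopsimError):
    """The integrated state became non-finite."""


class GraphError(PopsimError):
    """A PD graph contains a cycle or an unsupported motif."""


class ScanError(PopsimError):
    """An invalid sensitivity-analysis scan specification."""


class FitError(PopsimError):
    """An invalid parameter-estimation specification."""
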