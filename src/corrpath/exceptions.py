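"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class CorrpathError(Exception):
    """Base class for all package errors."""


class ConfigError(CorrpathError):
    """Bad run configuration (missing files, out-of-range numeric fields)."""


class DataValidationError(CorrpathError):
    """Input data violates an invariant (labels, shapes, numeric cells)."""


class SolverError(CorrpathError):
    """An optimization model could not be solved (infeasible/unbounded)."""


class SolverLimitError(SolverError):
    """Time limit hit before an optimality certificate was obtained.

    Carries the incumbent tour (may be ``None``) and the remaining gap so
    callers can inspect the best feasible solution without mistaking it
    for a certified optimum.
    """

    def __init__(self, message, incumbent=None, gap=None):
        super().__init__(message)
        self.incumbent = incumbent
        self.gap = gap
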