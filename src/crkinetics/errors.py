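"""Exception hierarchy shared across the kinetics pipeline."""


class CrKineticsError(Exception):
    """Base class for all package errors."""


class DomainError(CrKineticsError, ValueError):
    """Invalid parameter value or out-of-domain argument (negative S, t, ...)."""


class InsufficientDataError(CrKineticsError):
    """Too few usable observations for the requested estimate."""


class DegenerateDataError(CrKineticsError):
    """Data carry no signal for the requested statistic (e.g. zero total SS)."""


class ConvergenceError(CrKineticsError):
    """Every optimisation start failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class SimulationError(CrKineticsError):
    """ODE integration failure; carries the solver state dump."""

    def __init__(self, message: str, state=None):
        super().__init__(message)
        self.state = state


class ParseError(CrKineticsError):
    """Malformed input table; names the offending row where possible."""
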