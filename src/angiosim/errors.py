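"""Exception hierarchy shared across the simulator."""


class AngiosimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AngiosimError):
    """Invalid, unknown or inconsistent configuration entries.

    Carries the full list of problems so a bad config is reported once,
    not key by key.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class ConsistencyError(AngiosimError):
    """Agent or field state violates a structural invariant (e.g. an agent
    outside the grid, a missing environment species)."""


class NumericalError(AngiosimError):
    """A numerical scheme produced a non-finite or unstable state."""


class DomainError(AngiosimError, ValueError):
    """Scalar input outside the mathematical domain of an operation."""
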