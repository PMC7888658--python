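"""Exception hierarchy shared across the package."""


class NevosimError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(NevosimError, ValueError):
    """A parameter lies outside its admissible interval."""


class ConstructionError(NevosimError, RuntimeError):
    """A geometric object could not be built to its differentiability contract."""


class DomainError(NevosimError, ValueError):
    """A coordinate argument lies outside the valid domain."""


class OffManifoldError(NevosimError, ValueError):
    """A 3D point does not lie on the membrane surface within tolerance."""


class ContractViolationError(NevosimError, ValueError):
    """An input violates a documented operation precondition."""


class DomainExit(NevosimError):
    """Signal raised when a trajectory leaves the simulation extent.

    Callers discard the affected cell; this is control flow, not failure.
    """

    def __init__(self, u=None):
        super().__init__("path exited the simulation domain")
        self.u = u


class PackingError(NevosimError, RuntimeError):
    """Disk packing request is infeasible for the given extent."""


class FittingError(NevosimError, RuntimeError):
    """A statistical fit failed (e.g. degenerate sample)."""


class ConfigurationError(NevosimError, ValueError):
    """Simulation configuration is inconsistent or pathological."""
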