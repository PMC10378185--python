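"""Exception hierarchy shared across the package."""


class ClonesteerError(Exception):
    """Base class for package-specific errors."""


class InvalidParameterError(ClonesteerError, ValueError):
    """Growth or model parameters violate their domain constraints."""


class IntegrationError(ClonesteerError, RuntimeError):
    """The ODE solver failed to produce a trajectory."""


class EmptyMatrixError(ClonesteerError, ValueError):
    """A filtering step removed every cell (or the input had none)."""


class SeedingError(ClonesteerError, ValueError):
    """A passage seeds the culture at or above the shared capacity surface,
    violating the precondition sum_i N_i(0)/K_i < 1 that guarantees
    nonnegative growth."""


class ConfoundedDesignError(ClonesteerError, ValueError):
    """Synthetic driver gene sets overlap, confounding r and K signals."""
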