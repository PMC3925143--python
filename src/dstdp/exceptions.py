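"""Exception types raised across the package."""


class ParameterError(ValueError):
    """A model or input parameter violates its constraints."""


class ResolutionError(ParameterError):
    """The time step is too coarse for the requested rates or AP duration."""


class StateCorruptionError(RuntimeError):
    """Simulation state violates an invariant (e.g. a negative weight)."""


class NumericalInstabilityError(RuntimeError):
    """The membrane integration diverged; reports the offending time step."""

    def __init__(self, dt: float, message: str | None = None):
        self.dt = dt
        super().__init__(message or f"membrane potential diverged (dt={dt} ms)")


class InstanceTooLargeError(RuntimeError):
    """The brute-force pairing oracle was asked for too many spike pairs."""
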