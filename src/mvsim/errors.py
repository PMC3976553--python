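"""Exception hierarchy for the simulator."""


class MVSimError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MVSimError, ValueError):
    """A physical or numerical parameter violates its admissibility conditions."""


class ConfigurationError(MVSimError, ValueError):
    """A run configuration is inconsistent or references missing entities."""


class MeshError(MVSimError, ValueError):
    """A mesh violates a validity invariant (degenerate element, bad index, ...)."""


class SimulationError(MVSimError, RuntimeError):
    """The time integration failed (NaN, inverted element, ...)."""


class FitError(MVSimError, RuntimeError):
    """Constitutive parameter fitting failed or is underdetermined."""


class InputError(MVSimError, ValueError):
    """A post-processing input is missing or malformed."""
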