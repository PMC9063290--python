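"""Exception types shared across the package."""


class TmasAdaptError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TmasAdaptError, ValueError):
    """A physical parameter violates a hard invariant (e.g. nonpositive density)."""


class InvalidStateError(TmasAdaptError, ValueError):
    """A neuron state is unusable (non-finite voltage, gate far outside [0, 1])."""


class DegenerateStateError(TmasAdaptError, ValueError):
    """A state that makes an expression singular (e.g. Ca = -30 in the AHP term)."""


class ConfigurationError(TmasAdaptError, ValueError):
    """A simulation configuration is inconsistent (e.g. dt too coarse for f_u)."""


class EquilibriumSearchError(TmasAdaptError, RuntimeError):
    """The resting-state search failed to converge."""


class DivergenceError(TmasAdaptError, RuntimeError):
    """The membrane potential left the physical range during integration."""


class InsufficientSpikesError(TmasAdaptError, ValueError):
    """A spike-train statistic was requested with too few spikes."""


class InsufficientDurationError(TmasAdaptError, ValueError):
    """A synthetic train was requested over a window too short to hold two spikes."""


class TemplateOverlapError(TmasAdaptError, ValueError):
    """Spike templates overlap when rendering a synthetic membrane trace."""


class InfeasibleGeometryError(TmasAdaptError, ValueError):
    """A synthetic burst pattern does not fit into its period."""
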