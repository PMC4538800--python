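"""Exception hierarchy for srnaspike."""


class SrnaSpikeError(Exception):
    """Base class for all srnaspike errors."""


class AlphabetError(SrnaSpikeError):
    """A sequence contains characters outside the allowed alphabet."""


class ParameterError(SrnaSpikeError):
    """An operation was called with an invalid parameter."""


class DesignInfeasibleError(SrnaSpikeError):
    """Rejection sampling exhausted its iteration cap.

    Carries the name of the constraint that rejected most candidates so the
    caller can see which filter is binding.
    """

    def __init__(self, message: str, binding_constraint: str | None = None):
        super().__init__(message)
        self.binding_constraint = binding_constraint


class RebalanceError(SrnaSpikeError):
    """Mix rebalancing failed (e.g. an oligo had zero observed reads)."""


class NormalizationError(SrnaSpikeError):
    """Normalization failed (zero totals, no usable reference features, ...)."""


class SamplingError(SrnaSpikeError):
    """Requested more reads than are available."""


class InsufficientDataError(SrnaSpikeError):
    """Too few defined data points to compute a statistic."""


class SimulationError(SrnaSpikeError):
    """A simulation scenario is degenerate (e.g. empty effective pool)."""


class InputError(SrnaSpikeError):
    """Malformed user input (duplicate ids, mismatched samples, ...)."""
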