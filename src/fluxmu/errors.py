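"""Exception hierarchy for fluxmu."""


class FluxmuError(Exception):
    """Base class for all fluxmu errors."""


class InvalidCompositionError(FluxmuError, ValueError):
    """A derivative composition has negative or inconsistent atom counts."""


class UndefinedRatioError(FluxmuError, ZeroDivisionError):
    """A ratio (isotopologue fraction, interference share) has a zero denominator."""


class InsufficientDataError(FluxmuError, ValueError):
    """Too few data points for the requested estimate."""


class NetworkValidationError(FluxmuError, ValueError):
    """A network file failed atom-balance or connectivity validation."""


class SingularNetworkError(FluxmuError, ArithmeticError):
    """A labeling balance is singular (zero throughput through a pool)."""


class UnidentifiableFluxError(FluxmuError, ArithmeticError):
    """The Fisher information of the fit is singular; some flux is unidentifiable."""


class OptimizationFailureError(FluxmuError, RuntimeError):
    """No feasible optimum was found from any start point."""


class ScenarioError(FluxmuError, ValueError):
    """A measurement scenario produced an unusable measurement set."""
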