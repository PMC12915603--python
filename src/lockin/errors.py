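"""Exception types shared across the package."""


class LockinError(Exception):
    """Base class for package errors."""


class CurveError(LockinError, ValueError):
    """Invalid influence-curve construction or evaluation outside [0, 1]."""


class EstimationError(LockinError, RuntimeError):
    """An estimator could not be computed from the available data
    (e.g. an empty central bin, so the marginal majority effect is undefined)."""


class UndeterminedError(EstimationError):
    """A binned curve carries no data in the region needed for the query."""
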