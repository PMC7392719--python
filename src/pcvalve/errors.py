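"""Exception hierarchy for pcvalve."""


class PCValveError(Exception):
    """Base class for all pcvalve errors."""


class InvalidParameterError(PCValveError, ValueError):
    """A physical or configuration parameter is outside its valid domain."""


class GeometryError(PCValveError, ValueError):
    """The requested jet geometry does not fit the acquisition grid."""


class NoJetError(PCValveError, RuntimeError):
    """No jet signal could be detected in a velocity-map series."""


class InsufficientDataError(PCValveError, ValueError):
    """Too few samples/frames/beats/subjects for the requested computation."""


class UndefinedStatisticError(PCValveError, ValueError):
    """The requested statistic is undefined for the given data (e.g. zero variance)."""
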