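"""Exception hierarchy for springwalker."""


class SpringWalkerError(Exception):
    """Base class for all springwalker errors."""


class InvalidStateError(SpringWalkerError, ValueError):
    """A walker state contains non-finite or otherwise invalid entries."""


class InvalidParameterError(SpringWalkerError, ValueError):
    """A model or filter parameter is outside its admissible range."""


class GaitRangeError(SpringWalkerError, ValueError):
    """Step length or walking speed outside the admissible open interval (0, 1)."""


class NoCollisionError(SpringWalkerError, RuntimeError):
    """No heel-strike event occurred before the swing-time cap.

    Signals a parameter combination for which the model does not walk
    (the walker falls, or the swing leg never lands ahead of the stance foot).
    """


class SolverError(SpringWalkerError, RuntimeError):
    """A root-finding or Newton iteration failed to converge.

    The last iterate, when available, is attached as ``last_iterate``.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class NoGaitError(SolverError):
    """No periodic gait exists for the requested step length / speed target."""


class SweepError(SpringWalkerError, RuntimeError):
    """Every grid point of a stiffness sweep failed to converge."""


class InsufficientDataError(SpringWalkerError, ValueError):
    """Too few observations for the requested fit or statistic."""


class RegressionError(SpringWalkerError, ValueError):
    """Degenerate input to a regression (zero variance, non-positive periods)."""


class NoEventsError(SpringWalkerError, ValueError):
    """No gait events could be detected in a force signal."""


class GeometryError(SpringWalkerError, ValueError):
    """Impossible step geometry (e.g. step length exceeding twice the leg length)."""


class SchemaError(SpringWalkerError, ValueError):
    """A trial directory or data table does not match the documented layout."""


class NonPhysicalPushOffWarning(UserWarning):
    """The push-off impulse required to sustain the map contract is negative."""
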