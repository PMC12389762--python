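"""Exception hierarchy for nwirecal.

The CLI maps these onto exit codes: input/format problems -> 2,
insufficient structure in the data -> 3, robust-estimation failure -> 4.
"""


class NWireCalError(Exception):
    """Base class for all nwirecal errors."""


class DegenerateGeometryError(NWireCalError, ValueError):
    """A geometric construction is degenerate (e.g. coincident points,
    a wire lying inside the image plane)."""


class AlphaRangeError(NWireCalError, ValueError):
    """The in-image distance ratio alpha falls outside the accepted
    [-tol, 1+tol] band, signalling a mislabeled triplet."""


class InsufficientStructureError(NWireCalError, ValueError):
    """Too few collinear triplets (or correspondences) to proceed."""


class UnderdeterminedError(InsufficientStructureError):
    """Fewer scalar equations than unknowns in the calibration solve."""


class InitializationFailureError(NWireCalError, RuntimeError):
    """No finite-residual initialization could be found."""


class RobustFailureError(NWireCalError, RuntimeError):
    """RANSAC finished without finding any inliers."""


class FormatError(NWireCalError, ValueError):
    """An input file violates its documented format."""


class ConfigurationError(NWireCalError, ValueError):
    """An invalid configuration (e.g. the phantom cannot be placed in view)."""


class IllConditionedWarning(UserWarning):
    """The pose set lacks rotational diversity; the 14-parameter problem
    may be poorly conditioned."""
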