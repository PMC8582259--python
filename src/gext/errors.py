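"""Exception hierarchy for gext."""


class GExtError(Exception):
    """Base class for all gext-specific errors."""


class LinearDependenceError(GExtError):
    """Overlap matrix is (numerically) singular: the basis is linearly dependent."""


class InjectivityDomainError(GExtError):
    """A subspace lies outside the injectivity domain of the Grassmann logarithm
    at the current reference point (a principal angle reached pi/2)."""


class RankDeficientFrameError(GExtError):
    """A matrix that should span an N-dimensional subspace is rank deficient."""


class TangentSpaceError(GExtError):
    """A putative tangent vector violates the horizontality condition C0^T Gamma = 0."""


class ConvergenceError(GExtError):
    """An iterative procedure failed to reach its tolerance within max_iter."""
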