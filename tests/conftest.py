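import numpy as np
import pytest

from gext.manifold import grassmann_exp


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_frame(rng, n_basis, n_occ):
    """A uniformly random Stiefel frame via QR of a Gaussian matrix."""
    A = rng.normal(size=(n_basis, n_occ))
    Q, R = np.linalg.qr(A)
    # fix gauge so the frame is deterministic given the Gaussian draw
    return Q * np.sign(np.diag(R))


def random_frame_pair(rng, n_basis, n_occ, min_cos=0.02):
    """Two random frames whose principal angles are safely below pi/2."""
    for _ in range(100):
        c0 = random_frame(rng, n_basis, n_occ)
        c1 = random_frame(rng, n_basis, n_occ)
        if np.min(np.linalg.svd(c0.T @ c1, compute_uv=False)) > min_cos:
            return c0, c1
    raise RuntimeError("could not sample a frame pair inside the injectivity domain")


def random_tangent(rng, c0, max_angle=1.4):
    """A random horizontal tangent vector at c0 with principal angles < pi/2."""
    n_basis, n_occ = c0.shape
    raw = rng.normal(size=(n_basis, n_occ))
    horiz = raw - c0 @ (c0.T @ raw)
    u, s, vt = np.linalg.svd(horiz, full_matrices=False)
    s = max_angle * s / np.max(s) * rng.uniform(0.2, 1.0)
    return (u * s) @ vt


def geodesic_frame(rng, c0, max_angle=1.4):
    """A frame a random geodesic step away from c0."""
    return grassmann_exp(c0, random_tangent(rng, c0, max_angle))
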