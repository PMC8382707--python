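import numpy as np
import pytest

from cochleashape.curves import Curve3D


def helix_curve(r=1.0, pitch=1.0, turns=2.0, n=500, specimen_id="helix"):
    t = np.linspace(0.0, turns * 2 * np.pi, n)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t), pitch * t])
    return Curve3D(points=pts, specimen_id=specimen_id)


def random_smooth_curve(rng, n=300, n_modes=3):
    """Random smooth open 3D curve from a low-order Fourier series.

    Amplitudes fall off as 1/k^2 so the curves are as well resolved at
    100-200 samples as digitized cochlear midlines are.
    """
    t = np.linspace(0.0, 1.0, n)
    pts = np.zeros((n, 3))
    for k in range(1, n_modes + 1):
        amp = rng.normal(scale=1.0 / k**2, size=(3, 2))
        pts += np.outer(np.sin(2 * np.pi * k * t), amp[:, 0]).reshape(n, 3)
        pts += np.outer(np.cos(2 * np.pi * k * t), amp[:, 1]).reshape(n, 3)
    pts += np.outer(t, rng.normal(scale=1.0, size=3))  # open drift term
    return Curve3D(points=pts, specimen_id="rnd")


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def default_study():
    """Default synthetic study bundle (shared; generation is cheap)."""
    from cochleashape.simulate import generate_study

    return generate_study(seed=1)
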