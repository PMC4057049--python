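import numpy as np
import pytest

from kneescrew import gen_stance_trial, screw_from_axis


def random_screw(rng, pitch_scale=0.05, span=0.5):
    """A generic finite-pitch screw near the origin."""
    return screw_from_axis(
        rng.uniform(-span, span, 3), rng.normal(size=3),
        pitch_scale * rng.normal())


def random_pose(rng, span=0.5):
    """A uniformly random proper rotation and a bounded translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.uniform(-span, span, 3)


def axis_angle_deg(u, v):
    """Unsigned angle between two line directions in degrees."""
    return np.degrees(np.arccos(np.clip(abs(np.dot(u, v)), -1.0, 1.0)))


@pytest.fixture(scope="session")
def noiseless_trial():
    """One noiseless synthetic stance trial shared across tests."""
    return gen_stance_trial(11)
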