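import numpy as np
import pytest

from cephaloplane import DeformationSpec, make_subject
from cephaloplane.reference_planes import build_reference_planes


@pytest.fixture
def symmetric_subject():
    """Undeformed template: the symmetric null of every asymmetry metric."""
    ls, truth = make_subject()
    return ls, truth


@pytest.fixture
def symmetric_planes(symmetric_subject):
    ls, _ = symmetric_subject
    return build_reference_planes(ls)


@pytest.fixture
def deviated_subject():
    """6.6 mm rightward chin deviation plus a 3 degree occlusal cant."""
    spec = DeformationSpec(chin_deviation_mm=6.6, occlusal_cant_deg=3.0)
    return make_subject(spec=spec)


def random_rigid(rng):
    """Seeded random proper rotation + translation."""
    from cephaloplane.geometry import RigidTransform

    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return RigidTransform(Q, rng.normal(scale=30.0, size=3))
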