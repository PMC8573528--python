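import numpy as np
import pytest

from sparsecap import LabeledPoints, RigidTransform, load_builtin
from sparsecap.geometry import rotation_about_axis


@pytest.fixture(scope="session")
def angles64():
    return load_builtin("ten_twenty_64")


@pytest.fixture(scope="session")
def angles128():
    return load_builtin("radial_128")


def canonical_points() -> LabeledPoints:
    """Eight-marker set already satisfying every local-frame invariant:
    electrodes on a 90 mm sphere (equatorial ring at z = 0, Cz at the pole),
    fiducials orthogonal with the LPA/RPA midpoint at the origin."""
    return LabeledPoints({
        "Cz": (0.0, 0.0, 90.0),
        "FPz": (0.0, 90.0, 0.0),
        "Oz": (0.0, -90.0, 0.0),
        "T7": (-90.0, 0.0, 0.0),
        "T8": (90.0, 0.0, 0.0),
        "Nz": (0.0, 95.0, 0.0),
        "LPA": (-70.0, 0.0, 0.0),
        "RPA": (70.0, 0.0, 0.0),
    })


@pytest.fixture
def canonical_markers():
    return canonical_points()


def random_rigid_transform(rng: np.random.Generator) -> RigidTransform:
    axis = rng.normal(size=3)
    angle = rng.uniform(-np.pi, np.pi)
    t = rng.uniform(-500, 500, size=3)
    return RigidTransform(rotation_about_axis(axis, angle), t)
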