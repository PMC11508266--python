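from __future__ import annotations

import numpy as np
import pytest

import punctureplan as pp


@pytest.fixture(scope="session")
def soft_ball_labels():
    """Homogeneous soft-tissue ball (radius 12 mm) in air, target at center."""
    # ball center on a voxel center so the target sits exactly at the middle
    spec = pp.PhantomSpec(
        shape=(32, 32, 32),
        body=pp.Ellipsoid(center_mm=(16.5, 16.5, 16.5), semiaxes_mm=(12.0, 12.0, 12.0), hu=20.0),
        target=pp.VoxelIndex(16, 16, 16),
    )
    phantom = pp.make_phantom(spec)
    labels = pp.mark_target(pp.classify_and_label(phantom), spec.target)
    return spec, labels


@pytest.fixture(scope="session")
def default_labels():
    """The default demo phantom (organ, airway, rib), classified and marked."""
    spec = pp.default_phantom_spec((40, 40, 40))
    phantom = pp.make_phantom(spec)
    labels = pp.mark_target(pp.classify_and_label(phantom), spec.target)
    return spec, phantom, labels


def make_two_gap_setup():
    """Bone shell around the target with a narrow hole towards +x (near skin)
    and a wide hole towards -x (far skin): the shortest and the safe route
    must disagree."""
    c = (24.5, 24.5, 24.5)
    spec = pp.PhantomSpec(
        shape=(48, 48, 48),
        body=pp.Ellipsoid(center_mm=(19.0, 24.5, 24.5), semiaxes_mm=(16.0, 18.0, 18.0),
                          hu=20.0),
        bone_shapes=(pp.SphericalShell(c, 6.0, 9.0, hu=400.0,
                                       holes=(((1.0, 0.0, 0.0), 15.0),
                                              ((-1.0, 0.0, 0.0), 40.0))),),
        target=pp.VoxelIndex(24, 24, 24),
    )
    phantom = pp.make_phantom(spec)
    labels = pp.mark_target(pp.classify_and_label(phantom), spec.target)
    return labels, spec


@pytest.fixture(scope="session")
def two_gap_setup():
    return make_two_gap_setup()


def random_segment(rng, shape, spacing, margin=0.05):
    """A random segment whose origin is strictly inside the volume."""
    extent = np.asarray(shape) * np.asarray(spacing)
    origin = rng.uniform(margin, 1 - margin, size=3) * extent
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    t_end = rng.uniform(0.5, 1.5) * float(np.linalg.norm(extent))
    return origin, v, t_end
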