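"""Shared fixtures: small hand-built models and session-scoped synthetic
trials (expensive to generate, reused across test modules)."""

import numpy as np
import pytest

from markerreg.kinematics import RigidTransform
from markerreg.model import (
    Axis,
    Joint,
    KinematicModel,
    Segment,
    robot_fixture,
)
from markerreg.synthetic import GaitSpec, make_dataset


def free_root(child: str = "base") -> Joint:
    """Standard 6-DOF free joint attaching ``child`` to ground."""
    eye = np.eye(3)
    return Joint(
        name="root",
        parent_segment="ground",
        child_segment=child,
        frame_in_parent=RigidTransform(eye, np.zeros(3)),
        frame_in_child=RigidTransform(eye, np.zeros(3)),
        axes=[
            Axis((1, 0, 0), "translation", "tx"),
            Axis((0, 1, 0), "translation", "ty"),
            Axis((0, 0, 1), "translation", "tz"),
            Axis((0, 0, 1), "rotation", "rz"),
            Axis((1, 0, 0), "rotation", "rx"),
            Axis((0, 1, 0), "rotation", "ry"),
        ],
    )


def hinge(name, parent, child, origin, axis=(0, 0, 1), coordinate=None):
    eye = np.eye(3)
    return Joint(
        name=name,
        parent_segment=parent,
        child_segment=child,
        frame_in_parent=RigidTransform(eye, origin),
        frame_in_child=RigidTransform(eye, np.zeros(3)),
        axes=[Axis(axis, "rotation", coordinate or name)],
    )


def two_link_chain(link_length: float = 1.0) -> KinematicModel:
    """Planar chain: base at the root, two links along +X with Z hinges.

    Coordinates: 6 root + q1 (hinge at origin) + q2 (hinge at link end).
    The distal marker 'tip' sits at the end of link2.
    """
    base = Segment(name="base")
    link1 = Segment(name="link1", markers={"elbow": (link_length, 0, 0)})
    link2 = Segment(name="link2", markers={"tip": (link_length, 0, 0)})
    return KinematicModel(
        [base, link1, link2],
        [
            free_root("base"),
            hinge("q1", "base", "link1", (0, 0, 0)),
            hinge("q2", "link1", "link2", (link_length, 0, 0)),
        ],
    )


def pin_with_markers(markers: dict, link_name: str = "link") -> KinematicModel:
    """Root-fixed base plus one Z-hinge link carrying the given markers."""
    base = Segment(
        name="base",
        markers={"B1": (0.2, 0, 0), "B2": (-0.2, 0, 0.1), "B3": (0, 0.2, -0.1)},
    )
    link = Segment(name=link_name, markers=markers)
    return KinematicModel(
        [base, link],
        [free_root("base"), hinge("pin", "base", link_name, (0, 0, 0))],
    )


@pytest.fixture(scope="session")
def robot():
    return robot_fixture()


@pytest.fixture(scope="session")
def gait_spec():
    return GaitSpec()


@pytest.fixture(scope="session")
def clean_trial(gait_spec):
    """Noise-free synthetic experiment at the study conditions."""
    return make_dataset(gait_spec, noise_sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def in_range_q(robot):
    """A deterministic in-range robot pose away from any singularity."""
    rng = np.random.default_rng(2024)
    q = np.zeros(robot.n_coordinates)
    idx = {n: i for i, n in enumerate(robot.coordinate_names)}
    q[idx["pelvis_tx"]] = 0.3
    q[idx["pelvis_ty"]] = 0.5
    q[idx["pelvis_tz"]] = -0.05
    for name, i in idx.items():
        if name.startswith("pelvis_t"):
            continue
        if name.startswith("pelvis"):
            q[i] = rng.uniform(-0.2, 0.2)
        elif "knee" in name:
            q[i] = rng.uniform(0.3, 1.0)
        else:
            q[i] = rng.uniform(-0.4, 0.4)
    return q
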