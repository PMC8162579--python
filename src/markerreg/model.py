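"""Rigid-body kinematic-chain data model and its JSON file representation.

A :class:`KinematicModel` is a tree of rigid :class:`Segment` objects joined
by :class:`Joint` objects and rooted at an implicit fixed ``ground`` body.
The root joint is a 6-DOF free joint (three translations then three
rotations) connecting the pelvis to ground; every other joint carries one to
three successive hinge axes, or none (a weld).

Generalized coordinates are ordered: root translations (m), root rotations
(rad), then joint coordinates (rad) in joint declaration order. Coordinate
vectors are plain ``numpy`` arrays; the model owns the ordering (see
``coordinate_names``).

The canonical humanoid-robot fixture (:func:`robot_fixture`) is a child-sized
biped with twelve lower-extremity degrees of freedom — three per hip, one per
knee, two per ankle — and a 35-marker set. Its link lengths and inertial
properties are documented stand-ins at child-like anthropometric proportions
(leg length ≈ 0.5 m) chosen so the gait generator can take 0.33 m steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import ModelParseError, ModelValidationError
from .kinematics import RigidTransform

GROUND = "ground"
SCHEMA_VERSION = 1

ROTATION = "rotation"
TRANSLATION = "translation"


@dataclass
class Axis:
    """One motion axis of a joint: a unit direction plus a coordinate name."""

    direction: np.ndarray
    kind: str
    coordinate: str

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        if self.kind not in (ROTATION, TRANSLATION):
            raise ModelValidationError(
                f"axis '{self.coordinate}': kind must be rotation|translation"
            )


@dataclass
class Joint:
    name: str
    parent_segment: str
    child_segment: str
    frame_in_parent: RigidTransform
    frame_in_child: RigidTransform
    axes: List[Axis] = field(default_factory=list)

    @property
    def coordinate_names(self) -> List[str]:
        return [a.coordinate for a in self.axes]


@dataclass
class Segment:
    name: str
    mass: float = 0.0
    com_local: np.ndarray = field(default_factory=lambda: np.zeros(3))
    inertia_local: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    markers: Dict[str, np.ndarray] = field(default_factory=dict)
    parent_joint: Optional[str] = None  # filled in by the model

    def __post_init__(self) -> None:
        self.com_local = np.asarray(self.com_local, dtype=float).reshape(3)
        self.inertia_local = np.asarray(self.inertia_local, dtype=float).reshape(3, 3)
        self.markers = {
            k: np.asarray(v, dtype=float).reshape(3) for k, v in self.markers.items()
        }


class KinematicModel:
    """Tree of rigid segments; validates all structural invariants on build."""

    def __init__(
        self,
        segments: Sequence[Segment],
        joints: Sequence[Joint],
        gravity=(0.0, -9.80665, 0.0),
        name: str = "model",
    ):
        self.name = name
        self.gravity = np.asarray(gravity, dtype=float).reshape(3)
        self.ground = GROUND
        self.segments: Dict[str, Segment] = {}
        for seg in segments:
            if seg.name in self.segments or seg.name == GROUND:
                raise ModelValidationError(f"duplicate segment name '{seg.name}'")
            self.segments[seg.name] = seg
        self.joints: Dict[str, Joint] = {}
        for joint in joints:
            if joint.name in self.joints:
                raise ModelValidationError(f"duplicate joint name '{joint.name}'")
            self.joints[joint.name] = joint
        self._validate()
        self._coordinate_names = [
            a.coordinate for j in self.joints.values() for a in j.axes
        ]
        self.coordinate_indices = {
            name: i for i, name in enumerate(self._coordinate_names)
        }
        self._marker_segment: Dict[str, str] = {}
        for seg in self.segments.values():
            for mname in seg.markers:
                if mname in self._marker_segment:
                    raise ModelValidationError(f"duplicate marker name '{mname}'")
                self._marker_segment[mname] = seg.name
        self._path_cache: Optional[Dict[str, np.ndarray]] = None

    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        roots = [j for j in self.joints.values() if j.parent_segment == GROUND]
        if len(roots) != 1:
            raise ModelValidationError(
                f"model must have exactly one ground-attached joint, found {len(roots)}"
            )
        root = roots[0]
        if next(iter(self.joints.values())) is not root:
            raise ModelValidationError("the root joint must be declared first")
        kinds = [a.kind for a in root.axes]
        if kinds != [TRANSLATION] * 3 + [ROTATION] * 3:
            raise ModelValidationError(
                "root joint must be a 6-DOF free joint: three translations "
                "then three rotations"
            )
        seen_coords: set = set()
        children: Dict[str, List[str]] = {}
        for joint in self.joints.values():
            for segref in (joint.parent_segment, joint.child_segment):
                if segref != GROUND and segref not in self.segments:
                    raise ModelValidationError(
                        f"joint '{joint.name}' references unknown segment '{segref}'"
                    )
            if joint is not root and len(joint.axes) > 3:
                raise ModelValidationError(
                    f"joint '{joint.name}': expected 0 (weld) to 3 axes"
                )
            for k, axis in enumerate(joint.axes):
                nrm = float(np.linalg.norm(axis.direction))
                if abs(nrm - 1.0) > 1e-9:
                    raise ModelValidationError(
                        f"joint '{joint.name}' axis '{axis.coordinate}' is not "
                        f"unit length (|a| = {nrm:.6g})"
                    )
                if axis.coordinate in seen_coords:
                    raise ModelValidationError(
                        f"duplicate coordinate name '{axis.coordinate}'"
                    )
                seen_coords.add(axis.coordinate)
                if k > 0 and joint.axes[k - 1].kind == axis.kind == ROTATION:
                    cosang = abs(
                        float(np.dot(joint.axes[k - 1].direction, axis.direction))
                    )
                    if cosang > 1.0 - 1e-9:
                        raise ModelValidationError(
                            f"joint '{joint.name}': consecutive rotation axes "
                            "are parallel"
                        )
            if not joint.frame_in_parent.is_proper() or not joint.frame_in_child.is_proper():
                raise ModelValidationError(
                    f"joint '{joint.name}': joint frames must be proper rigid "
                    "transforms"
                )
            children.setdefault(joint.parent_segment, []).append(joint.child_segment)
        # reachability / tree structure
        seen_parent: Dict[str, str] = {}
        for joint in self.joints.values():
            if joint.child_segment in seen_parent:
                raise ModelValidationError(
                    f"segment '{joint.child_segment}' has two parent joints"
                )
            seen_parent[joint.child_segment] = joint.name
        reached = set()
        stack = [GROUND]
        while stack:
            node = stack.pop()
            if node in reached:
                raise ModelValidationError("joint graph contains a cycle")
            reached.add(node)
            stack.extend(children.get(node, []))
        missing = set(self.segments) - reached
        if missing:
            raise ModelValidationError(
                f"segments unreachable from ground: {sorted(missing)}"
            )
        for seg in self.segments.values():
            seg.parent_joint = seen_parent[seg.name]
            if seg.mass < 0:
                raise ModelValidationError(f"segment '{seg.name}': negative mass")
            if not np.allclose(seg.inertia_local, seg.inertia_local.T, atol=1e-12):
                raise ModelValidationError(
                    f"segment '{seg.name}': inertia tensor not symmetric"
                )
            if np.linalg.eigvalsh(seg.inertia_local).min() < -1e-12:
                raise ModelValidationError(
                    f"segment '{seg.name}': inertia tensor not positive semidefinite"
                )

    # ------------------------------------------------------------------ #
    @property
    def coordinate_names(self) -> List[str]:
        return list(self._coordinate_names)

    @property
    def n_coordinates(self) -> int:
        return len(self._coordinate_names)

    @property
    def root_joint(self) -> Joint:
        return next(iter(self.joints.values()))

    @property
    def marker_names(self) -> List[str]:
        return list(self._marker_segment)

    @property
    def n_markers(self) -> int:
        return len(self._marker_segment)

    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments.values()))

    def coordinate_index(self, name: str) -> int:
        return self.coordinate_indices[name]

    def marker_segment(self, marker: str) -> str:
        try:
            return self._marker_segment[marker]
        except KeyError:
            raise KeyError(f"unknown marker '{marker}'") from None

    def marker_offset(self, marker: str) -> np.ndarray:
        return self.segments[self.marker_segment(marker)].markers[marker]

    def parent_of(self, segment: str) -> str:
        return self.joints[self.segments[segment].parent_joint].parent_segment

    def path_coordinates(self) -> Dict[str, np.ndarray]:
        """Per segment: indices of coordinates on the path from ground."""
        if self._path_cache is None:
            path: Dict[str, list] = {GROUND: []}
            for joint in self.joints.values():
                own = [self.coordinate_indices[a.coordinate] for a in joint.axes]
                path[joint.child_segment] = path[joint.parent_segment] + own
            self._path_cache = {
                k: np.asarray(v, dtype=int) for k, v in path.items()
            }
        return self._path_cache

    def copy(self) -> "KinematicModel":
        return KinematicModel.from_dict(self.to_dict())

    def with_marker_offsets(self, offsets: Dict[str, np.ndarray]) -> "KinematicModel":
        """New model with the given markers moved to new local offsets."""
        new = self.copy()
        for name, off in offsets.items():
            seg = new.segments[new.marker_segment(name)]
            seg.markers[name] = np.asarray(off, dtype=float).reshape(3)
        return new

    # ------------------------------- serialization -------------------- #
    def to_dict(self) -> dict:
        def tf(t: RigidTransform) -> dict:
            return {
                "rotation": t.rotation.tolist(),
                "translation": t.translation.tolist(),
            }

        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "gravity": self.gravity.tolist(),
            "segments": [
                {
                    "name": s.name,
                    "mass": s.mass,
                    "com_local": s.com_local.tolist(),
                    "inertia_local": s.inertia_local.tolist(),
                    "markers": [
                        {"name": m, "offset": off.tolist()}
                        for m, off in s.markers.items()
                    ],
                }
                for s in self.segments.values()
            ],
            "joints": [
                {
                    "name": j.name,
                    "parent": j.parent_segment,
                    "child": j.child_segment,
                    "frame_in_parent": tf(j.frame_in_parent),
                    "frame_in_child": tf(j.frame_in_child),
                    "axes": [
                        {
                            "direction": a.direction.tolist(),
                            "kind": a.kind,
                            "coordinate": a.coordinate,
                        }
                        for a in j.axes
                    ],
                }
                for j in self.joints.values()
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @staticmethod
    def from_dict(data: dict) -> "KinematicModel":
        def need(obj: dict, key: str, where: str):
            if key not in obj:
                raise ModelParseError(f"missing key '{key}' in {where}")
            return obj[key]

        if int(need(data, "schema_version", "model file")) != SCHEMA_VERSION:
            raise ModelParseError(
                f"unsupported schema_version {data['schema_version']}"
            )

        def tf(obj: dict, where: str) -> RigidTransform:
            return RigidTransform(
                need(obj, "rotation", where), need(obj, "translation", where)
            )

        segments = []
        for sd in need(data, "segments", "model file"):
            where = f"segment '{sd.get('name', '?')}'"
            segments.append(
                Segment(
                    name=need(sd, "name", "segment entry"),
                    mass=float(sd.get("mass", 0.0)),
                    com_local=sd.get("com_local", (0.0, 0.0, 0.0)),
                    inertia_local=sd.get("inertia_local", np.zeros((3, 3))),
                    markers={
                        need(m, "name", f"marker in {where}"): need(
                            m, "offset", f"marker in {where}"
                        )
                        for m in sd.get("markers", [])
                    },
                )
            )
        joints = []
        for jd in need(data, "joints", "model file"):
            where = f"joint '{jd.get('name', '?')}'"
            joints.append(
                Joint(
                    name=need(jd, "name", "joint entry"),
                    parent_segment=need(jd, "parent", where),
                    child_segment=need(jd, "child", where),
                    frame_in_parent=tf(need(jd, "frame_in_parent", where), where),
                    frame_in_child=tf(need(jd, "frame_in_child", where), where),
                    axes=[
                        Axis(
                            need(a, "direction", f"axis in {where}"),
                            need(a, "kind", f"axis in {where}"),
                            need(a, "coordinate", f"axis in {where}"),
                        )
                        for a in jd.get("axes", [])
                    ],
                )
            )
        return KinematicModel(
            segments,
            joints,
            gravity=data.get("gravity", (0.0, -9.80665, 0.0)),
            name=data.get("name", "model"),
        )


def load_model(path) -> KinematicModel:
    """Load and validate a kinematic model from its JSON file representation."""
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    if not isinstance(data, dict):
        raise ModelParseError(f"{path}: top level must be a JSON object")
    return KinematicModel.from_dict(data)


def save_model(model: KinematicModel, path) -> None:
    """Write a model atomically (temp file then rename)."""
    from .fileio import atomic_write_text

    atomic_write_text(path, model.to_json() + "\n")


# ---------------------------------------------------------------------- #
#  Canonical humanoid-robot fixture
# ---------------------------------------------------------------------- #

# Fixture geometry (meters). Child-like proportions; leg (hip→ankle) 0.51 m.
THIGH_LENGTH = 0.26
SHANK_LENGTH = 0.25
HIP_HALF_SPACING = 0.082
ANKLE_HEIGHT = 0.06  # ankle joint center above the sole / ground plane
FOOT_SOLE_DROP = 0.05  # foot markers sit this far below the ankle center


def _cylinder_inertia(mass: float, radius: float, length: float) -> np.ndarray:
    """Solid cylinder about its COM, long axis = local Y."""
    ixx = izz = mass * (3 * radius**2 + length**2) / 12.0
    iyy = mass * radius**2 / 2.0
    return np.diag([ixx, iyy, izz])


def _box_inertia(mass: float, lx: float, ly: float, lz: float) -> np.ndarray:
    return np.diag(
        [
            mass * (ly**2 + lz**2) / 12.0,
            mass * (lx**2 + lz**2) / 12.0,
            mass * (lx**2 + ly**2) / 12.0,
        ]
    )


def _leg(side: str) -> tuple:
    """Segments and joints of one leg. ``side`` ∈ {'r', 'l'}."""
    zeta = 1.0 if side == "r" else -1.0
    s = side
    eye = np.eye(3)

    def mirror(v):
        return np.array([v[0], v[1], zeta * v[2]])

    femur = Segment(
        name=f"femur_{s}",
        mass=1.6,
        com_local=(0.0, -0.11, 0.0),
        inertia_local=_cylinder_inertia(1.6, 0.035, THIGH_LENGTH),
        markers={
            f"{s.upper()}THI": mirror((0.035, -0.10, 0.045)),
            f"{s.upper()}TH2": mirror((0.040, -0.17, 0.020)),
            f"{s.upper()}TH3": mirror((-0.020, -0.14, 0.048)),
            f"{s.upper()}KNL": mirror((0.0, -THIGH_LENGTH, 0.052)),
            f"{s.upper()}KNM": mirror((0.0, -THIGH_LENGTH, -0.052)),
        },
    )
    tibia = Segment(
        name=f"tibia_{s}",
        mass=0.9,
        com_local=(0.0, -0.11, 0.0),
        inertia_local=_cylinder_inertia(0.9, 0.03, SHANK_LENGTH),
        markers={
            f"{s.upper()}TIB": mirror((0.038, -0.08, 0.028)),
            f"{s.upper()}TB2": mirror((0.030, -0.16, 0.045)),
            f"{s.upper()}TB3": mirror((-0.018, -0.12, 0.040)),
            f"{s.upper()}ANL": mirror((0.0, -SHANK_LENGTH, 0.046)),
            f"{s.upper()}ANM": mirror((0.0, -SHANK_LENGTH, -0.046)),
        },
    )
    foot = Segment(
        name=f"foot_{s}",
        mass=0.25,
        com_local=mirror((0.03, -0.03, 0.0)),
        inertia_local=_box_inertia(0.25, 0.16, 0.05, 0.06),
        markers={
            f"{s.upper()}HEE": mirror((-0.045, -FOOT_SOLE_DROP + 0.005, 0.0)),
            f"{s.upper()}TOE": mirror((0.110, -FOOT_SOLE_DROP + 0.005, 0.010)),
            f"{s.upper()}MT5": mirror((0.070, -FOOT_SOLE_DROP + 0.010, 0.038)),
        },
    )
    # pseudovector mirroring: (x, y, z) -> (-x, -y, z) for the left side
    def axdir(v):
        return np.array([zeta * v[0], zeta * v[1], v[2]])

    hip = Joint(
        name=f"hip_{s}",
        parent_segment="pelvis",
        child_segment=f"femur_{s}",
        frame_in_parent=RigidTransform(eye, (0.0, 0.0, zeta * HIP_HALF_SPACING)),
        frame_in_child=RigidTransform(eye, np.zeros(3)),
        axes=[
            Axis((0.0, 0.0, 1.0), ROTATION, f"hip_flexion_{s}"),
            Axis(axdir((1.0, 0.0, 0.0)), ROTATION, f"hip_adduction_{s}"),
            Axis(axdir((0.0, -1.0, 0.0)), ROTATION, f"hip_rotation_{s}"),
        ],
    )
    knee = Joint(
        name=f"knee_{s}",
        parent_segment=f"femur_{s}",
        child_segment=f"tibia_{s}",
        frame_in_parent=RigidTransform(eye, (0.0, -THIGH_LENGTH, 0.0)),
        frame_in_child=RigidTransform(eye, np.zeros(3)),
        axes=[Axis((0.0, 0.0, -1.0), ROTATION, f"knee_flexion_{s}")],
    )
    ankle = Joint(
        name=f"ankle_{s}",
        parent_segment=f"tibia_{s}",
        child_segment=f"foot_{s}",
        frame_in_parent=RigidTransform(eye, (0.0, -SHANK_LENGTH, 0.0)),
        frame_in_child=RigidTransform(eye, np.zeros(3)),
        axes=[
            Axis((0.0, 0.0, 1.0), ROTATION, f"ankle_flexion_{s}"),
            Axis(axdir((1.0, 0.0, 0.0)), ROTATION, f"ankle_inversion_{s}"),
        ],
    )
    return [femur, tibia, foot], [hip, knee, ankle]


def robot_fixture() -> KinematicModel:
    """The canonical child-sized 12-DOF biped with its 35-marker set.

    Deterministic: two calls produce identical models. Marker distribution:
    3 per foot, 3 per shank + 2 ankle-axis, 3 per thigh + 2 knee-axis,
    4 pelvis, 2 trunk, 3 head (= 35). Sign conventions (right-handed, Y up,
    X forward): hip/ankle flexion positive about +Z for dorsiflexion-like
    motion, knee flexion positive (axis −Z), adduction positive toward the
    midline on both sides, internal rotation positive on both sides.
    """
    eye = np.eye(3)
    pelvis = Segment(
        name="pelvis",
        mass=2.2,
        com_local=(0.0, 0.04, 0.0),
        inertia_local=_box_inertia(2.2, 0.12, 0.10, 0.20),
        markers={
            "RASI": (0.080, 0.020, 0.070),
            "LASI": (0.080, 0.020, -0.070),
            "RPSI": (-0.090, 0.030, 0.040),
            "LPSI": (-0.090, 0.030, -0.040),
        },
    )
    trunk = Segment(
        name="trunk",
        mass=6.0,
        com_local=(0.0, 0.14, 0.0),
        inertia_local=_box_inertia(6.0, 0.14, 0.28, 0.18),
        markers={"STRN": (0.070, 0.10, 0.0), "C7": (-0.060, 0.22, 0.0)},
    )
    head = Segment(
        name="head",
        mass=1.8,
        com_local=(0.0, 0.06, 0.0),
        inertia_local=_box_inertia(1.8, 0.12, 0.14, 0.12),
        markers={
            "RFHD": (0.060, 0.080, 0.040),
            "LFHD": (0.060, 0.080, -0.040),
            "BKHD": (-0.070, 0.060, 0.0),
        },
    )
    root = Joint(
        name="ground_pelvis",
        parent_segment=GROUND,
        child_segment="pelvis",
        frame_in_parent=RigidTransform(eye, np.zeros(3)),
        frame_in_child=RigidTransform(eye, np.zeros(3)),
        axes=[
            Axis((1.0, 0.0, 0.0), TRANSLATION, "pelvis_tx"),
            Axis((0.0, 1.0, 0.0), TRANSLATION, "pelvis_ty"),
            Axis((0.0, 0.0, 1.0), TRANSLATION, "pelvis_tz"),
            Axis((0.0, 0.0, 1.0), ROTATION, "pelvis_tilt"),
            Axis((1.0, 0.0, 0.0), ROTATION, "pelvis_list"),
            Axis((0.0, 1.0, 0.0), ROTATION, "pelvis_rotation"),
        ],
    )
    back = Joint(
        name="back",
        parent_segment="pelvis",
        child_segment="trunk",
        frame_in_parent=RigidTransform(eye, (0.0, 0.09, 0.0)),
        frame_in_child=RigidTransform(eye, np.zeros(3)),
        axes=[],
    )
    neck = Joint(
        name="neck",
        parent_segment="trunk",
        child_segment="head",
        frame_in_parent=RigidTransform(eye, (0.0, 0.30, 0.0)),
        frame_in_child=RigidTransform(eye, np.zeros(3)),
        axes=[],
    )
    segs_r, joints_r = _leg("r")
    segs_l, joints_l = _leg("l")
    return KinematicModel(
        segments=[pelvis, trunk, head, *segs_r, *segs_l],
        joints=[root, *joints_r, *joints_l, back, neck],
        name="humanoid_robot_12dof",
    )


def bundled_data_path(name: str):
    """Path to a bundled data file, e.g. ``robot.model.json``."""
    from importlib import resources

    return resources.files("markerreg") / "data" / name


# Right-leg degrees of freedom compared throughout the evaluation protocol.
RIGHT_LEG_COORDS = [
    "hip_flexion_r",
    "hip_adduction_r",
    "hip_rotation_r",
    "knee_flexion_r",
    "ankle_flexion_r",
    "ankle_inversion_r",
]

# The twelve actuated (encoder-instrumented) joint coordinates.
JOINT_COORDS = [
    f"{j}_{s}"
    for s in ("r", "l")
    for j in (
        "hip_flexion",
        "hip_adduction",
        "hip_rotation",
        "knee_flexion",
        "ankle_flexion",
        "ankle_inversion",
    )
]
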