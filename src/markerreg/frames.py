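"""Anatomical reference frames from optical marker subsets.

A :class:`FrameDefinition` names an origin (a marker or a midpoint of
markers), a primary direction (kept exact), and a secondary direction
(orthogonalized by Gram–Schmidt); the third axis is the cross product
chosen so the resulting triad is right-handed. Each direction is a vector
between two marker centroids and is mapped onto a named axis (``x``/``y``/
``z``) of the frame.

The bundled definitions for the robot fixture follow the classic
marker-triad conventions used in gait analysis: the pelvis frame from the
ASIS/PSIS markers, thigh and shank mediolateral axes from the knee- and
ankle-flexion-axis marker pairs, and the foot long axis from heel and toe
markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np

from .errors import DegenerateFrameError, ModelParseError
from .fileio import MarkerFrameSeries, atomic_write_text
from .kinematics import RigidTransform

_AXES = ("x", "y", "z")
# minimum subtended angle between the two defining directions
MIN_ANGLE_RAD = np.deg2rad(1.0)


@dataclass
class AxisSpec:
    """A direction from the centroid of ``start`` to the centroid of ``end``,
    assigned to the named frame axis."""

    start: List[str]
    end: List[str]
    axis: str

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis label must be one of {_AXES}")


@dataclass
class FrameDefinition:
    segment: str
    origin: List[str]
    primary: AxisSpec
    secondary: AxisSpec

    def __post_init__(self) -> None:
        if self.primary.axis == self.secondary.axis:
            raise ValueError("primary and secondary must map to different axes")

    @property
    def marker_names(self) -> List[str]:
        seen: List[str] = []
        for name in (
            *self.origin,
            *self.primary.start,
            *self.primary.end,
            *self.secondary.start,
            *self.secondary.end,
        ):
            if name not in seen:
                seen.append(name)
        return seen


@dataclass
class AnatomicalFrame:
    """A segment's anatomical frame expressed in another frame (usually ground)."""

    segment: str
    transform: RigidTransform


def _centroid(names: Sequence[str], markers: Dict[str, np.ndarray]) -> np.ndarray:
    try:
        return np.mean([np.asarray(markers[n], dtype=float) for n in names], axis=0)
    except KeyError as exc:
        raise KeyError(f"missing marker {exc} for frame construction") from None


def _third_axis_sign(primary: str, secondary: str) -> float:
    """+1 if (primary, secondary, third) is an even permutation of (x, y, z)."""
    third = ({"x", "y", "z"} - {primary, secondary}).pop()
    perm = (primary, secondary, third)
    even = perm in (("x", "y", "z"), ("y", "z", "x"), ("z", "x", "y"))
    return 1.0 if even else -1.0


def build_frame(
    definition: FrameDefinition, marker_positions: Dict[str, np.ndarray]
) -> AnatomicalFrame:
    """Right-handed orthonormal frame from marker positions by Gram–Schmidt.

    The primary direction is kept exact; the secondary is orthogonalized
    against it; the third axis completes the right-handed triad. Raises
    :class:`DegenerateFrameError` if the two directions subtend < 1°.
    """
    origin = _centroid(definition.origin, marker_positions)
    u1 = _centroid(definition.primary.end, marker_positions) - _centroid(
        definition.primary.start, marker_positions
    )
    u2 = _centroid(definition.secondary.end, marker_positions) - _centroid(
        definition.secondary.start, marker_positions
    )
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateFrameError(
            f"segment '{definition.segment}': zero-length axis direction"
        )
    u1 = u1 / n1
    u2 = u2 / n2
    cross = np.cross(u1, u2)
    if np.linalg.norm(cross) < np.sin(MIN_ANGLE_RAD):
        raise DegenerateFrameError(
            f"segment '{definition.segment}': defining directions subtend "
            "less than 1 degree"
        )
    u2 = u2 - (u2 @ u1) * u1
    u2 = u2 / np.linalg.norm(u2)
    u3 = _third_axis_sign(definition.primary.axis, definition.secondary.axis) * np.cross(
        u1, u2
    )
    rotation = np.empty((3, 3))
    rotation[:, _AXES.index(definition.primary.axis)] = u1
    rotation[:, _AXES.index(definition.secondary.axis)] = u2
    third = ({"x", "y", "z"} - {definition.primary.axis, definition.secondary.axis}).pop()
    rotation[:, _AXES.index(third)] = u3
    return AnatomicalFrame(definition.segment, RigidTransform(rotation, origin))


def frames_from_static(
    static_series: MarkerFrameSeries,
    definitions: Sequence[FrameDefinition],
    markerset: Sequence[str] | None = None,
) -> Dict[str, AnatomicalFrame]:
    """Segment frames from a static trial: markers are time-averaged first."""
    if static_series.n_frames < 1:
        raise ValueError("static trial must contain at least one frame")
    mean = static_series.mean_positions()
    if markerset is not None:
        unknown = set(static_series.names) - set(markerset)
        if unknown:
            raise KeyError(f"static trial has markers not in the model: {sorted(unknown)}")
    return {d.segment: build_frame(d, mean) for d in definitions}


def model_frames(model, definitions: Sequence[FrameDefinition]) -> Dict[str, AnatomicalFrame]:
    """Anatomical frames expressed in each segment's own frame, computed from
    the model's local marker offsets (the model-side counterpart of
    :func:`frames_from_static`, representing known construction geometry)."""
    out = {}
    for d in definitions:
        local = {}
        for name in d.marker_names:
            seg = model.marker_segment(name)
            if seg != d.segment:
                raise ValueError(
                    f"frame for '{d.segment}' references marker '{name}' on "
                    f"segment '{seg}'"
                )
            local[name] = model.marker_offset(name)
        out[d.segment] = build_frame(d, local)
    return out


# ------------------------------- file I/O ------------------------------ #


def _axis_spec_to_dict(a: AxisSpec) -> dict:
    return {"start": a.start, "end": a.end, "axis": a.axis}


def save_frame_definitions(definitions: Sequence[FrameDefinition], path) -> None:
    payload = {
        "schema_version": 1,
        "frames": [
            {
                "segment": d.segment,
                "origin": d.origin,
                "primary": _axis_spec_to_dict(d.primary),
                "secondary": _axis_spec_to_dict(d.secondary),
            }
            for d in definitions
        ],
    }
    atomic_write_text(path, json.dumps(payload, indent=1) + "\n")


def load_frame_definitions(path) -> List[FrameDefinition]:
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    try:
        return [
            FrameDefinition(
                segment=d["segment"],
                origin=list(d["origin"]),
                primary=AxisSpec(**d["primary"]),
                secondary=AxisSpec(**d["secondary"]),
            )
            for d in data["frames"]
        ]
    except KeyError as exc:
        raise ModelParseError(f"{path}: missing key {exc}") from None


def default_frame_definitions() -> List[FrameDefinition]:
    """Bundled frame definitions for the robot fixture.

    Anatomical axis labels: in the neutral standing pose every frame aligns
    with the world convention — x anterior, y up, z toward the subject's
    right. Thigh and shank mediolateral axes come from the knee- and
    ankle-flexion-axis marker pairs (medial → lateral on the right side,
    lateral → medial on the left, so +z always points right).
    """
    defs = [
        FrameDefinition(
            segment="pelvis",
            origin=["RASI", "LASI"],
            primary=AxisSpec(["LASI"], ["RASI"], "z"),
            secondary=AxisSpec(["RPSI", "LPSI"], ["RASI", "LASI"], "x"),
        )
    ]
    for s in ("r", "l"):
        u = s.upper()
        med, lat = (f"{u}KNM", f"{u}KNL") if s == "r" else (f"{u}KNL", f"{u}KNM")
        amed, alat = (f"{u}ANM", f"{u}ANL") if s == "r" else (f"{u}ANL", f"{u}ANM")
        foot_z = (
            AxisSpec([f"{u}TOE"], [f"{u}MT5"], "z")
            if s == "r"
            else AxisSpec([f"{u}MT5"], [f"{u}TOE"], "z")
        )
        defs.append(
            FrameDefinition(
                segment=f"femur_{s}",
                origin=[f"{u}KNM", f"{u}KNL"],
                primary=AxisSpec([med], [lat], "z"),
                secondary=AxisSpec([f"{u}KNM", f"{u}KNL"], [f"{u}THI"], "y"),
            )
        )
        defs.append(
            FrameDefinition(
                segment=f"tibia_{s}",
                origin=[f"{u}ANM", f"{u}ANL"],
                primary=AxisSpec([amed], [alat], "z"),
                secondary=AxisSpec([f"{u}ANM", f"{u}ANL"], [f"{u}TIB"], "y"),
            )
        )
        defs.append(
            FrameDefinition(
                segment=f"foot_{s}",
                origin=[f"{u}HEE"],
                primary=AxisSpec([f"{u}HEE"], [f"{u}TOE"], "x"),
                secondary=foot_z,
            )
        )
    return defs
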