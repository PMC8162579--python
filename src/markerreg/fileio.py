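"""Readers and writers for the motion-capture interchange formats.

TRC (marker trajectories) and MOT/STO (time-series tables: coordinates,
ground reactions, moments) in the common OpenSim-flavored dialect:
tab-delimited, TRC positions in millimeters, MOT tables with an
``endheader`` sentinel and an ``inDegrees`` declaration that applies to
rotational columns. All in-memory values are SI (meters, radians, seconds);
unit conversion happens only here.

All writes are atomic: content goes to a temporary file in the destination
directory which is then renamed over the target.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import FileFormatError


def atomic_write_text(path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename in one directory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------- #
#  Marker series
# ---------------------------------------------------------------------- #


@dataclass
class MarkerFrameSeries:
    """Time-indexed world positions of named markers (the content of a TRC).

    ``positions`` has shape (n_frames, n_markers, 3) in meters; missing
    observations are NaN triplets. Sampling must be uniform.
    """

    names: List[str]
    time: np.ndarray
    positions: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float).reshape(-1)
        self.positions = np.asarray(self.positions, dtype=float)
        n = self.time.size
        if self.positions.shape != (n, len(self.names), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{n} frames × {len(self.names)} markers"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("marker names must be unique")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(np.abs(dt - 1.0 / self.rate) > 1e-6):
                raise ValueError("sampling must be uniform at the declared rate")

    @property
    def n_frames(self) -> int:
        return self.time.size

    def frame(self, i: int) -> Dict[str, np.ndarray]:
        """Named positions at frame ``i``; missing markers are omitted."""
        out = {}
        for j, name in enumerate(self.names):
            p = self.positions[i, j]
            if not np.any(np.isnan(p)):
                out[name] = p
        return out

    def mean_positions(self) -> Dict[str, np.ndarray]:
        """Per-marker time-average over the series, ignoring missing frames."""
        out = {}
        for j, name in enumerate(self.names):
            col = self.positions[:, j, :]
            good = ~np.any(np.isnan(col), axis=1)
            if good.any():
                out[name] = col[good].mean(axis=0)
        return out


def write_trc(series: MarkerFrameSeries, path, units: str = "mm") -> None:
    scale = {"mm": 1000.0, "m": 1.0}[units]
    n, m = series.n_frames, len(series.names)
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{series.rate:g}\t{series.rate:g}\t{n}\t{m}\t{units}\t{series.rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(series.names) + "\t\t",
        "\t\t" + "\t".join(
            f"X{j+1}\tY{j+1}\tZ{j+1}" for j in range(m)
        ),
        "",
    ]
    for i in range(n):
        cells = [str(i + 1), f"{series.time[i]:.6f}"]
        for j in range(m):
            p = series.positions[i, j] * scale
            if np.any(np.isnan(p)):
                cells.extend(["", "", ""])
            else:
                cells.extend(f"{v:.6f}" for v in p)
        lines.append("\t".join(cells))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_trc(path) -> MarkerFrameSeries:
    path = Path(path)
    with open(path) as fh:
        raw = fh.read().splitlines()
    if len(raw) < 6:
        raise FileFormatError(f"{path}: truncated TRC header")
    meta_keys = raw[1].split("\t")
    meta_vals = raw[2].split("\t")
    if "Units" not in meta_keys:
        raise FileFormatError(f"{path}: line 2: missing 'Units' in TRC header")
    meta = dict(zip(meta_keys, meta_vals))
    units = meta.get("Units", "mm")
    if units not in ("mm", "m"):
        raise FileFormatError(f"{path}: line 3: unsupported units '{units}'")
    scale = {"mm": 1e-3, "m": 1.0}[units]
    try:
        rate = float(meta["DataRate"])
        n_markers = int(meta["NumMarkers"])
    except (KeyError, ValueError) as exc:
        raise FileFormatError(f"{path}: line 3: bad TRC metadata") from exc
    header_cells = raw[3].split("\t")
    names = [c for c in header_cells[2:] if c.strip()]
    if len(names) != n_markers:
        raise FileFormatError(
            f"{path}: line 4: {len(names)} marker labels, header declares "
            f"{n_markers}"
        )
    rows, times = [], []
    for lineno, line in enumerate(raw[5:], start=6):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < 2:
            raise FileFormatError(f"{path}: line {lineno}: too few columns")
        expected = 2 + 3 * n_markers
        if len(cells) != expected:
            # trailing tabs may be trimmed; pad blanks
            if len(cells) < expected:
                cells = cells + [""] * (expected - len(cells))
            else:
                raise FileFormatError(
                    f"{path}: line {lineno}: {len(cells)} columns, expected "
                    f"{expected}"
                )
        times.append(float(cells[1]))
        vals = []
        for c in cells[2:]:
            c = c.strip()
            vals.append(float(c) if c else np.nan)
        rows.append(vals)
    pos = np.asarray(rows).reshape(len(rows), n_markers, 3) * scale
    return MarkerFrameSeries(names, np.asarray(times), pos, rate)


# ---------------------------------------------------------------------- #
#  MOT / STO tables
# ---------------------------------------------------------------------- #


@dataclass
class MotTable:
    """A generic MOT/STO table: a time column plus named data columns.

    Values are stored exactly as they appear in the file; ``in_degrees``
    records the header declaration so callers can convert rotational
    columns (see :func:`table_to_radians`).
    """

    names: List[str]
    time: np.ndarray
    data: np.ndarray
    in_degrees: bool = False
    name: str = "table"

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.names.index(name)]


def write_mot(table: MotTable, path) -> None:
    n, m = table.data.shape
    lines = [
        table.name,
        "version=1",
        f"nRows={n}",
        f"nColumns={m + 1}",
        f"inDegrees={'yes' if table.in_degrees else 'no'}",
        "endheader",
        "time\t" + "\t".join(table.names),
    ]
    for i in range(n):
        lines.append(
            f"{table.time[i]:.8f}\t"
            + "\t".join(f"{v:.8f}" for v in table.data[i])
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_mot(path) -> MotTable:
    path = Path(path)
    with open(path) as fh:
        raw = fh.read().splitlines()
    header = {}
    body_start = None
    for i, line in enumerate(raw):
        if line.strip() == "endheader":
            body_start = i + 1
            break
        if "=" in line:
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
    if body_start is None:
        raise FileFormatError(f"{path}: missing 'endheader' sentinel")
    cols = raw[body_start].split("\t")
    if not cols or cols[0].strip().lower() != "time":
        raise FileFormatError(f"{path}: first column must be 'time'")
    names = [c.strip() for c in cols[1:] if c.strip()]
    rows = []
    for lineno, line in enumerate(raw[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(names) + 1:
            raise FileFormatError(
                f"{path}: line {lineno}: {len(cells)} columns, expected "
                f"{len(names) + 1}"
            )
        rows.append([float(c) for c in cells])
    arr = np.asarray(rows, dtype=float)
    if "nRows" in header and int(header["nRows"]) != arr.shape[0]:
        raise FileFormatError(
            f"{path}: nRows={header['nRows']} but {arr.shape[0]} data rows"
        )
    return MotTable(
        names=names,
        time=arr[:, 0],
        data=arr[:, 1:],
        in_degrees=header.get("inDegrees", "no").lower() == "yes",
        name=raw[0].strip() if raw else "table",
    )


def table_to_radians(table: MotTable, angle_columns: Sequence[str]) -> MotTable:
    """Copy of ``table`` with the named columns guaranteed to be in radians."""
    data = table.data.copy()
    if table.in_degrees:
        for name in angle_columns:
            if name in table.names:
                data[:, table.names.index(name)] = np.deg2rad(
                    data[:, table.names.index(name)]
                )
    return MotTable(list(table.names), table.time.copy(), data, False, table.name)


# ---------------------------------------------------------------------- #
#  Ground-reaction tables (OpenSim external-loads dialect)
# ---------------------------------------------------------------------- #

GRF_COMPONENTS = (
    "ground_force_vx",
    "ground_force_vy",
    "ground_force_vz",
    "ground_force_px",
    "ground_force_py",
    "ground_force_pz",
    "ground_torque_x",
    "ground_torque_y",
    "ground_torque_z",
)


def grf_to_table(grfs: Sequence, prefixes: Optional[Sequence[str]] = None) -> MotTable:
    """Pack GroundReaction series (one per plate) into a 9-column-per-plate table."""
    if prefixes is None:
        prefixes = [g.applied_body for g in grfs]
    time = grfs[0].time
    names, blocks = [], []
    for g, pre in zip(grfs, prefixes):
        if g.time.shape != time.shape or np.any(np.abs(g.time - time) > 1e-9):
            raise ValueError("all plates must share one time base")
        names.extend(f"{pre}_{c}" for c in GRF_COMPONENTS)
        blocks.append(np.hstack([g.force, g.cop, g.free_moment]))
    return MotTable(names, time.copy(), np.hstack(blocks), False, "ground_reactions")


def table_to_grf(table: MotTable, prefix: str, applied_body: str):
    """Extract one plate's GroundReaction from a 9-column block."""
    from .dynamics import GroundReaction

    cols = [f"{prefix}_{c}" for c in GRF_COMPONENTS]
    missing = [c for c in cols if c not in table.names]
    if missing:
        raise FileFormatError(f"missing ground-reaction columns: {missing}")
    block = np.column_stack([table.column(c) for c in cols])
    return GroundReaction(
        time=table.time.copy(),
        force=block[:, 0:3],
        cop=block[:, 3:6],
        free_moment=block[:, 6:9],
        applied_body=applied_body,
    )
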