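"""Lightweight coordinate-frame containers and text readers/writers.

Positions are stored in nm. Boxes are orthorhombic cubes (single edge
length); the minimum-image convention is applied wherever a box is given.
Only the two plain-text formats needed by the pipeline are supported:
XYZ (assumed to be in nm) and GRO (nm by definition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass
class CoordinateFrame:
    """One frame of named particles.

    Attributes
    ----------
    names : list of str
        Per-particle labels (atom or particle names).
    positions : ndarray, shape (n, 3)
        Cartesian coordinates in nm.
    """

    names: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if len(self.names) != len(self.positions):
            raise ValueError("names and positions length mismatch")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class CoordinateFrameSet:
    """A sequence of frames sharing particle identities and a cubic box."""

    frames: list[CoordinateFrame] = field(default_factory=list)
    box_edge: float | None = None  # nm

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box_edge: float | None
) -> np.ndarray:
    """Displacement b - a under the minimum-image convention (cubic box)."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box_edge is not None:
        d -= box_edge * np.round(d / box_edge)
    return d


def write_xyz(frameset: CoordinateFrameSet, path: str | Path) -> None:
    """Write frames as multi-frame XYZ (coordinates in nm)."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in frameset:
            fh.write(f"{len(frame)}\n")
            comment = "frame"
            if frameset.box_edge is not None:
                comment += f" box_edge_nm={frameset.box_edge:g}"
            fh.write(comment + "\n")
            for name, pos in zip(frame.names, frame.positions):
                fh.write(f"{name} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}\n")


def read_xyz(path: str | Path, box_edge: float | None = None) -> CoordinateFrameSet:
    """Read a multi-frame XYZ file; coordinates are taken as nm.

    A ``box_edge_nm=<x>`` token in a comment line is honoured unless
    ``box_edge`` is passed explicitly.
    """
    path = Path(path)
    frames: list[CoordinateFrame] = []
    parsed_edge: float | None = None
    with path.open() as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        for token in comment.split():
            if token.startswith("box_edge_nm="):
                parsed_edge = float(token.split("=", 1)[1])
        names: list[str] = []
        coords: list[list[float]] = []
        for line in lines[i + 2 : i + 2 + n]:
            parts = line.split()
            names.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(CoordinateFrame(names, np.array(coords)))
        i += 2 + n
    edge = box_edge if box_edge is not None else parsed_edge
    return CoordinateFrameSet(frames, box_edge=edge)


def read_gro(path: str | Path, box_edge: float | None = None) -> CoordinateFrameSet:
    """Read a (possibly multi-frame) GRO file; positions in nm.

    The box edge is taken from the first component of the final box
    vector line unless overridden.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    frames: list[CoordinateFrame] = []
    edge = box_edge
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i + 1].strip())
        names: list[str] = []
        coords: list[list[float]] = []
        for line in lines[i + 2 : i + 2 + n]:
            # fixed columns: resid(5) resname(5) atomname(5) atomnum(5) x y z
            names.append(line[10:15].strip())
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
            coords.append([x, y, z])
        box_line = lines[i + 2 + n].split()
        if edge is None and box_line:
            edge = float(box_line[0])
        frames.append(CoordinateFrame(names, np.array(coords)))
        i += 3 + n
    return CoordinateFrameSet(frames, box_edge=edge)


def select_by_name(frame: CoordinateFrame, names: Iterable[str]) -> np.ndarray:
    """Indices of particles whose name is in ``names``."""
    wanted = set(names)
    return np.array([i for i, n in enumerate(frame.names) if n in wanted], dtype=int)


def mass_weighted_com(
    positions: np.ndarray, masses: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Mass-weighted centre of mass of a position array."""
    m = np.asarray(masses, dtype=float)
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    return (positions * m[:, None]).sum(axis=0) / m.sum()
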