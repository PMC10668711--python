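"""Pen geometry, zone partition and microphone-array layout.

The monitored scene is a farrowing pen of 2.80 x 1.75 m containing a
farrowing crate of 2.1 x 1.0 m, observed by an overhead acoustic camera
(a planar array of 64 microphones).  Coordinates are continuous metres
with the origin at a pen corner: x runs along the 2.80 m pen axis with
the sow's head at low x, y across the 1.75 m width, z upward from the
floor.  Sound sources are modelled on the floor plane (z = 0).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

SPEED_OF_SOUND = 343.0  # m/s, dry air at ~20 C


class Zone(str, Enum):
    """Named regions of the pen plane used to judge spot locations.

    ``cloud`` is not positional: it marks a burst of many near-simultaneous
    spots.  ``none`` is the in-pen floor area outside any named region.
    """

    HEAD = "head"
    RUMP = "rump"
    FENCE = "fence"
    TROUGH = "trough"
    OUTSIDE_PEN = "outside_pen"
    CLOUD = "cloud"
    NONE = "none"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


@dataclass(frozen=True)
class PenGeometry:
    """Dimensions of one farrowing pen and its crate.

    The crate sits centred across the pen width, its head end starting at
    ``sow_head_x``.  A feeding trough occupies the strip between the pen
    wall and the head end of the crate; a boundary strip of width
    ``fence_strip_m`` along the pen walls is the fence zone.
    """

    pen_length_m: float = 2.80
    pen_width_m: float = 1.75
    crate_length_m: float = 2.10
    crate_width_m: float = 1.00
    camera_height_m: float = 2.20
    sow_head_x: float = 0.30
    fence_strip_m: float = 0.15

    def __post_init__(self) -> None:
        lengths = (
            self.pen_length_m,
            self.pen_width_m,
            self.crate_length_m,
            self.crate_width_m,
            self.camera_height_m,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all pen/crate/camera dimensions must be > 0")
        if self.crate_length_m > self.pen_length_m or self.crate_width_m > self.pen_width_m:
            raise ValueError("crate dimensions must not exceed pen dimensions")
        if self.sow_head_x < 0 or self.sow_head_x + self.crate_length_m > self.pen_length_m:
            raise ValueError("crate (sow_head_x + crate_length_m) must fit inside the pen")

    # crate footprint ----------------------------------------------------
    @property
    def crate_x(self) -> tuple[float, float]:
        return (self.sow_head_x, self.sow_head_x + self.crate_length_m)

    @property
    def crate_y(self) -> tuple[float, float]:
        half = self.crate_width_m / 2.0
        mid = self.pen_width_m / 2.0
        return (mid - half, mid + half)

    @property
    def head_x(self) -> tuple[float, float]:
        """Front third of the crate (sow's head and shoulders)."""
        x0, x1 = self.crate_x
        return (x0, x0 + self.crate_length_m / 3.0)

    @property
    def rear_x(self) -> tuple[float, float]:
        """Rear third of the crate — the area behind the sow where piglets
        are born and move."""
        x0, x1 = self.crate_x
        return (x1 - self.crate_length_m / 3.0, x1)

    @property
    def array_center(self) -> tuple[float, float, float]:
        return (self.pen_length_m / 2.0, self.pen_width_m / 2.0, self.camera_height_m)


def zone_of(position: tuple[float, float], geometry: PenGeometry) -> Zone:
    """Deterministic, total partition of the pen plane into zones.

    Priority: outside the pen > trough > crate (head / rump) > fence strip
    > remaining floor (``none``).  The head zone is the front third of the
    crate; the remaining two thirds are the rump ("behind the sow").
    """
    x, y = float(position[0]), float(position[1])
    g = geometry
    if x < 0 or x > g.pen_length_m or y < 0 or y > g.pen_width_m:
        return Zone.OUTSIDE_PEN
    cy0, cy1 = g.crate_y
    if x < g.sow_head_x and cy0 <= y <= cy1:
        return Zone.TROUGH
    cx0, cx1 = g.crate_x
    if cx0 <= x <= cx1 and cy0 <= y <= cy1:
        hx0, hx1 = g.head_x
        return Zone.HEAD if x <= hx1 else Zone.RUMP
    s = g.fence_strip_m
    if x < s or x > g.pen_length_m - s or y < s or y > g.pen_width_m - s:
        return Zone.FENCE
    return Zone.NONE


@dataclass(frozen=True)
class MicArray:
    """Microphone coordinates of the acoustic camera, metres, shape (N, 3)."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n_mics, 3)")
        if len(np.unique(pos, axis=0)) != len(pos):
            raise ValueError("microphone positions must be distinct")
        object.__setattr__(self, "positions", pos)

    @property
    def n_mics(self) -> int:
        return int(self.positions.shape[0])


def overhead_array(
    geometry: PenGeometry,
    n_side: int = 8,
    pitch_m: float = 0.04,
    center: tuple[float, float, float] | None = None,
) -> MicArray:
    """Planar square microphone grid over the pen centre (default 8 x 8,
    0.04 m pitch, i.e. the 64-microphone camera), facing the floor."""
    if center is None:
        center = geometry.array_center
    offs = (np.arange(n_side) - (n_side - 1) / 2.0) * pitch_m
    gx, gy = np.meshgrid(offs, offs, indexing="ij")
    pos = np.column_stack(
        [gx.ravel() + center[0], gy.ravel() + center[1], np.full(n_side * n_side, center[2])]
    )
    return MicArray(pos)


def irregular_array(
    geometry: PenGeometry,
    n_mics: int = 64,
    aperture_m: float = 0.32,
    min_spacing_m: float = 0.028,
    layout_seed: int = 2026,
    center: tuple[float, float, float] | None = None,
) -> MicArray:
    """Irregular (Poisson-disk) planar 64-microphone layout — the default
    camera array.

    At ultrasonic wavelengths (~8 mm at 44 kHz) any periodic layout with
    centimetre pitch produces grating lobes of near-full height, making
    localisation ambiguous; commercial acoustic cameras therefore use
    irregular microphone layouts, which spread that aliased energy into a
    low (~1/sqrt(N)) sidelobe floor.  The layout is a fixed deterministic
    pattern (``layout_seed`` is part of the instrument, not of a scene).
    """
    if center is None:
        center = geometry.array_center
    rng = np.random.default_rng(layout_seed)
    half = aperture_m / 2.0
    pts: list[np.ndarray] = []
    while len(pts) < n_mics:
        p = rng.uniform(-half, half, 2)
        if all(np.hypot(*(p - q)) > min_spacing_m for q in pts):
            pts.append(p)
    xy = np.array(pts) + np.array(center[:2])
    pos = np.column_stack([xy, np.full(n_mics, center[2])])
    return MicArray(pos)


def distances(points: np.ndarray, mics: np.ndarray) -> np.ndarray:
    """Euclidean distances, shape (n_points, n_mics); 2-D points get z = 0."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    diff = pts[:, None, :] - np.asarray(mics, dtype=float)[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))
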