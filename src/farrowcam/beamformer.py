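"""Delay-and-sum beamforming onto the pen plane and sound-spot detection.

The acoustic camera's processing chain is reproduced in four steps: each
candidate floor point has a known propagation delay to every microphone
(distance / c); focusing a point means shifting every channel back by its
delay so that a source at the point sums in phase while other sources and
noise interfere destructively; the channel average is normalised by the
number of microphones and its peak magnitude over the frame becomes the
acoustic-map value at that point.  Per frame, the map maximum becomes a
sound spot if it stands far enough above the map's noise floor ("no clear
source" rule) and lies inside the spatial-filter region (one pen).
Detected spot times are shifted by a constant lag correction (+1.5 s by
default) compensating the recording lag of the spot stream.

Denoising selects one 2000-Hz frequency band inside the 39-49 kHz range
in which pen sounds stand out best; the per-camera bands used in the field
are available as :data:`CAMERA_BANDS`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from . import _kernels
from .geometry import SPEED_OF_SOUND, MicArray, PenGeometry, Zone, distances, zone_of

log = logging.getLogger(__name__)

#: the frequency range in which pen sounds were best visible
ULTRASONIC_RANGE = (39_000.0, 49_000.0)

#: manually tuned 2000-Hz analysis band per camera
CAMERA_BANDS = {
    "camera1": (39_570.0, 41_570.0),
    "camera2": (46_060.0, 48_060.0),
    "camera3": (41_730.0, 43_730.0),
    "camera1_study2": (45_630.0, 47_630.0),
}


@dataclass(frozen=True)
class BandConfig:
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        if self.f_lo < ULTRASONIC_RANGE[0] or self.f_hi > ULTRASONIC_RANGE[1]:
            log.info(
                "band %.0f-%.0f Hz lies outside the usual %.0f-%.0f Hz analysis range",
                self.f_lo, self.f_hi, *ULTRASONIC_RANGE,
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo

    @classmethod
    def camera(cls, name: str) -> "BandConfig":
        return cls(*CAMERA_BANDS[name])


@dataclass(frozen=True)
class DelayTable:
    """Propagation delays (s) from every grid point to every microphone."""

    grid_points: np.ndarray  # (P, 2) pen-plane coordinates, z = 0
    delays: np.ndarray  # (P, M) seconds
    c: float = SPEED_OF_SOUND

    @property
    def span_s(self) -> float:
        return float(self.delays.max() - self.delays.min())


@dataclass(frozen=True)
class AcousticMap:
    """Beamformed magnitudes over a rectangular pen-plane grid, one frame."""

    frame_time: float
    grid: np.ndarray  # (nx, ny) magnitudes, >= 0
    grid_spacing_m: float
    origin: tuple[float, float]  # pen coordinates of grid[0, 0]

    def argmax_position(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.grid)), self.grid.shape)
        return (self.origin[0] + i * self.grid_spacing_m, self.origin[1] + j * self.grid_spacing_m)

    @property
    def floor(self) -> float:
        return float(np.median(self.grid))


@dataclass(frozen=True)
class SoundSpot:
    t: float  # lag-corrected
    position: tuple[float, float]
    zone: Zone
    magnitude: float


@dataclass
class DetectorConfig:
    frame_len_s: float = 0.05
    hop_s: float = 0.05
    threshold_db_above_floor: float = 6.0
    lag_correction_s: float = 1.5
    #: (x0, x1, y0, y1) rectangle shown by the spatial filter; None = whole pen
    spatial_region: tuple[float, float, float, float] | None = None
    grid_spacing_m: float = 0.05
    #: the beamformer searches this far beyond the spatial region so that a
    #: source outside the region localises at its true (out-of-region)
    #: position and is then hidden by the filter, instead of leaking its
    #: sidelobes into the shown map
    search_margin_m: float = 0.8
    subsample: bool = True
    c: float = SPEED_OF_SOUND

    def __post_init__(self) -> None:
        if self.frame_len_s <= 0:
            raise ValueError("frame_len_s must be > 0")
        if self.hop_s <= 0 or self.hop_s > self.frame_len_s:
            raise ValueError("need 0 < hop_s <= frame_len_s")

    def region(self, geometry: PenGeometry) -> tuple[float, float, float, float]:
        if self.spatial_region is not None:
            return self.spatial_region
        return (0.0, geometry.pen_length_m, 0.0, geometry.pen_width_m)

    def search_region(self, geometry: PenGeometry) -> tuple[float, float, float, float]:
        x0, x1, y0, y1 = self.region(geometry)
        m = self.search_margin_m
        return (x0 - m, x1 + m, y0 - m, y1 + m)


# ---------------------------------------------------------------------------
# delays / grids
# ---------------------------------------------------------------------------
def make_grid(region: tuple[float, float, float, float], spacing: float):
    """Regular lattice over a rectangle; returns (points (P,2), shape, origin)."""
    x0, x1, y0, y1 = region
    xs = np.arange(x0, x1 + spacing / 2, spacing)
    ys = np.arange(y0, y1 + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()]), (len(xs), len(ys)), (float(xs[0]), float(ys[0]))


def compute_delays(array: MicArray, grid_points: np.ndarray, c: float = SPEED_OF_SOUND) -> DelayTable:
    """delay(g, m) = ||g - m|| / c for floor points g (z = 0)."""
    if c <= 0:
        raise ValueError("speed of sound must be > 0")
    pts = np.asarray(grid_points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    return DelayTable(grid_points=pts[:, :2], delays=distances(pts, array.positions) / c, c=c)


# ---------------------------------------------------------------------------
# band selection
# ---------------------------------------------------------------------------
@lru_cache(maxsize=16)
def _band_sos(f_lo: float, f_hi: float, fs: float):
    bw = f_hi - f_lo
    ws = [max(10.0, f_lo - bw / 2), min(0.499 * fs, f_hi + bw / 2)]
    # gpass is per pass; the zero-phase (forward-backward) application
    # doubles both it and the stopband attenuation
    sos = sps.iirdesign(
        wp=[f_lo, f_hi], ws=ws, gpass=0.5, gstop=30.0, ftype="ellip", output="sos", fs=fs
    )
    return sos


def band_filter(x: np.ndarray, band: BandConfig, fs: float) -> np.ndarray:
    """Zero-phase band-pass selecting the analysis band (>= 40 dB stop)."""
    if fs <= 2 * band.f_hi:
        raise ValueError("sampling rate must exceed twice the band's upper edge")
    sos = _band_sos(band.f_lo, band.f_hi, float(fs))
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


# ---------------------------------------------------------------------------
# beamforming
# ---------------------------------------------------------------------------
def das_beamform(
    frame: np.ndarray,
    delays: DelayTable,
    fs: float,
    frame_time: float = 0.0,
    start: int = 0,
    length: int | None = None,
    grid_shape: tuple[int, int] | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    spacing: float = 0.05,
    subsample: bool = True,
) -> AcousticMap:
    """Beamform one multichannel frame onto the delay table's grid.

    ``frame`` is (M, S); the aligned output window is samples
    ``[start, start + length)`` and the frame must extend past it by the
    largest delay (plus one sample for interpolation).
    """
    sig = np.ascontiguousarray(np.asarray(frame, dtype=np.float64))
    M, S = sig.shape
    if delays.delays.shape[1] != M:
        raise ValueError("delay table does not match the channel count")
    d_samp = delays.delays * fs
    if length is None:
        length = S - int(np.ceil(d_samp.max())) - 1 - start
    if length <= 0 or start + length + int(np.ceil(d_samp.max())) + 1 > S:
        raise ValueError("frame shorter than the output window plus the delay span")
    vals = _kernels.das_time_max(sig, d_samp, start, int(length), subsample)
    if grid_shape is None:
        n = len(delays.grid_points)
        grid_shape = (n, 1)
    return AcousticMap(
        frame_time=frame_time,
        grid=vals.reshape(grid_shape),
        grid_spacing_m=spacing,
        origin=origin,
    )


def das_beamform_reference(
    frame: np.ndarray, points: np.ndarray, array: MicArray, fs: float, c: float = SPEED_OF_SOUND,
    start: int = 0, length: int | None = None,
) -> np.ndarray:
    """Plain-numpy brute-force delay-and-sum (fractional delays via linear
    interpolation).  Independent of the compiled kernel; used as an oracle
    on dense grids and small problems."""
    sig = np.asarray(frame, dtype=np.float64)
    M, S = sig.shape
    d = distances(points, array.positions) / c * fs  # (P, M) samples
    if length is None:
        length = S - int(np.ceil(d.max())) - 1 - start
    t = np.arange(S)
    out = np.empty(len(d))
    k = np.arange(start, start + length)
    for p in range(len(d)):
        acc = np.zeros(length)
        for m in range(M):
            acc += np.interp(k + d[p, m], t, sig[m])
        out[p] = np.max(np.abs(acc)) / M
    return out


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------
def detect_spots(
    maps: list[AcousticMap],
    det: DetectorConfig,
    geometry: PenGeometry | None = None,
) -> list[SoundSpot]:
    """One spot per frame at most: the map maximum, if it exceeds the
    per-frame noise floor (median of the map) by the configured margin and
    falls inside the spatial-filter region."""
    g = geometry or PenGeometry()
    x0, x1, y0, y1 = det.region(g)
    thr = 10.0 ** (det.threshold_db_above_floor / 20.0)
    last_t = None
    spots: list[SoundSpot] = []
    for amap in maps:
        if last_t is not None and amap.frame_time < last_t:
            raise ValueError("acoustic maps must be time-ordered")
        last_t = amap.frame_time
        peak = float(amap.grid.max())
        if peak <= 0:
            continue
        floor = amap.floor
        if floor > 0 and peak < floor * thr:
            continue  # no clear source
        px, py = amap.argmax_position()
        if not (x0 <= px <= x1 and y0 <= py <= y1):
            continue  # spatial filter
        spots.append(
            SoundSpot(
                t=amap.frame_time + det.lag_correction_s,
                position=(px, py),
                zone=zone_of((px, py), g),
                magnitude=peak,
            )
        )
    return spots


def beamform_recording(
    signals: np.ndarray,
    fs: float,
    array: MicArray,
    geometry: PenGeometry,
    band: BandConfig | None,
    det: DetectorConfig,
    t0: float = 0.0,
    return_maps: bool = False,
):
    """Full time-domain pipeline for an in-memory recording: band-pass,
    frame, beamform every frame on the detection grid, detect spots.

    Intended for short recordings; long scenes go through
    :func:`farrowcam.scanner.scan_scene`.  Returns a spot list (and the
    per-frame maps when ``return_maps``).
    """
    sig = np.asarray(signals, dtype=np.float64)
    if band is not None:
        sig = band_filter(sig, band, fs)
    points, shape, origin = make_grid(det.search_region(geometry), det.grid_spacing_m)
    table = compute_delays(array, points, det.c)
    L = int(round(det.frame_len_s * fs))
    hop = int(round(det.hop_s * fs))
    dspan = int(np.ceil(table.delays.max() * fs)) + 2
    maps = []
    f = 0
    while f * hop + L + dspan <= sig.shape[1]:
        amap = das_beamform(
            sig, table, fs, frame_time=t0 + f * hop / fs, start=f * hop, length=L,
            grid_shape=shape, origin=origin, spacing=det.grid_spacing_m,
            subsample=det.subsample,
        )
        maps.append(amap)
        f += 1
    spots = detect_spots(maps, det, geometry)
    return (spots, maps) if return_maps else spots


def spots_to_log(spots: list[SoundSpot]):
    """Spot list -> shared event-log dialect (stream = ``spot``)."""
    from .annotation import EventLog

    return EventLog.from_records(
        [
            {
                "time_s": s.t,
                "duration_s": 0.0,
                "stream": "spot",
                "label": "spot",
                "zone": str(s.zone),
                "x_m": s.position[0],
                "y_m": s.position[1],
                "audible": False,
            }
            for s in spots
        ]
    )
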