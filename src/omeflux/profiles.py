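"""Axial intensity profiles, kymographs and demographs.

Quantification of rod-cell fluorescence works in one dimension: pixel values
are averaged perpendicular to the cell centerline to give an intensity
profile along the long axis, profiles over time become a kymograph (each
frame normalized to its own mean, which cancels acquisition photobleaching),
and collections of junction profiles sorted by junction length become a
demograph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .simcell import CellGeometry

__all__ = [
    "IntensityProfile",
    "Kymograph",
    "Junction",
    "JunctionProfileSet",
    "Demograph",
    "extract_profile",
    "kymograph",
    "normalize_dual",
    "demograph",
]


@dataclass
class IntensityProfile:
    """1-D fluorescence profile along a cell axis (positions um, intensity AU)."""

    s: np.ndarray
    intensity: np.ndarray
    channel: str = ""
    frame: int = 0

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s.shape != self.intensity.shape or self.s.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1-D vectors")
        if len(self.s) and np.any(np.diff(self.s) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.s))) if len(self.s) > 1 else np.nan

    @property
    def length(self) -> float:
        return float(self.s[-1] - self.s[0]) if len(self.s) else 0.0


def extract_profile(frame: np.ndarray, geometry: CellGeometry, averaging_width: float,
                    pixel_size: float, origin=(0.0, 0.0), channel: str = "",
                    frame_index: int = 0) -> IntensityProfile:
    """Axial intensity profile of one image frame.

    The intensity at arc position s is the mean of bilinearly interpolated
    pixel values sampled perpendicular to the centerline within
    ``averaging_width``; the axial sampling step equals ``pixel_size``, giving
    floor(L / pixel_size) + 1 samples.
    """
    if averaging_width < 0:
        raise ValueError("averaging_width must be >= 0")
    if averaging_width > geometry.width:
        raise ValueError("averaging_width must not exceed the cell width")
    frame = np.asarray(frame, dtype=float)
    origin = np.asarray(origin, dtype=float)
    ny, nx = frame.shape

    # validate that the centerline stays inside the frame, naming the vertex
    vpx = (geometry.centerline - origin) / pixel_size
    for i, (x, y) in enumerate(vpx):
        if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
            raise ValueError(
                f"centerline vertex {i} of cell {geometry.cell_id!r} at pixel "
                f"({x:.1f}, {y:.1f}) lies outside the {ny}x{nx} frame")

    L = geometry.length
    n_s = int(np.floor(L / pixel_size)) + 1
    s_grid = np.arange(n_s) * pixel_size
    if averaging_width > 0:
        n_off = max(3, 2 * int(np.ceil(averaging_width / pixel_size)) + 1)
        offsets = np.linspace(-averaging_width / 2, averaging_width / 2, n_off)
    else:
        offsets = np.array([0.0])

    centers = geometry.point_at(s_grid)
    normals = geometry.normal_at(s_grid)
    pts = centers[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    px = (pts - origin) / pixel_size  # (n_off, n_s, 2) in (x, y)
    coords = np.stack([px[..., 1].ravel(), px[..., 0].ravel()])  # (row, col)
    vals = ndimage.map_coordinates(frame, coords, order=1, mode="nearest")
    prof = vals.reshape(len(offsets), n_s).mean(axis=0)
    return IntensityProfile(s_grid, prof, channel=channel, frame=frame_index)


@dataclass
class Kymograph:
    """Position x frame matrix of per-frame mean-normalized intensity."""

    data: np.ndarray            # (n_positions, n_frames)
    s: np.ndarray               # um
    position_step: float        # um
    frame_interval: float       # s

    def column_means(self) -> np.ndarray:
        return self.data.mean(axis=0)


def kymograph(stack: Sequence[np.ndarray] | np.ndarray, geometry: CellGeometry,
              pixel_size: float, averaging_width: float | None = None,
              frame_interval: float = 1.0, origin=(0.0, 0.0)) -> Kymograph:
    """Build a kymograph from an image stack.

    Each frame's axial profile is divided by its own mean — the paper-style
    correction for intensity loss during acquisition — then profiles are
    stacked into a position x time matrix (every column has mean 1).
    """
    frames = np.asarray(stack, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("stack must contain >= 2 frames")
    if averaging_width is None:
        averaging_width = geometry.width * 0.8
    cols = []
    for i, frame in enumerate(frames):
        prof = extract_profile(frame, geometry, averaging_width, pixel_size,
                               origin=origin, frame_index=i)
        m = prof.intensity.mean()
        if m == 0:
            raise ValueError(f"frame {i} has zero mean intensity (degenerate image)")
        cols.append(prof.intensity / m)
        s_grid = prof.s
    return Kymograph(np.stack(cols, axis=1), s_grid, float(pixel_size),
                     float(frame_interval))


def normalize_dual(profiles: Sequence[IntensityProfile]) -> list[IntensityProfile]:
    """Peak-anchored normalization for one or two channel groups.

    Within each channel, the profile containing the channel's global peak is
    scaled so that peak equals 1, and every other profile of the channel is
    scaled by the same factor — relative signal across a series is preserved
    (output stays in AU).
    """
    if not profiles:
        raise ValueError("no profiles given")
    by_channel: dict[str, list[IntensityProfile]] = {}
    for p in profiles:
        by_channel.setdefault(p.channel, []).append(p)
    out: list[IntensityProfile] = []
    for ch, group in by_channel.items():
        peak = max(float(p.intensity.max(initial=-np.inf)) for p in group)
        if not peak > 0:
            raise ValueError(f"channel {ch!r} has no positive signal anywhere")
        for p in group:
            out.append(IntensityProfile(p.s.copy(), p.intensity / peak,
                                        channel=p.channel, frame=p.frame))
    return out


@dataclass
class Junction:
    """One cell-cell junction: one or two channel profiles on a shared grid."""

    profiles: dict[str, IntensityProfile]

    def __post_init__(self):
        if not self.profiles:
            raise ValueError("junction needs at least one channel")
        grids = [p.s for p in self.profiles.values()]
        for g in grids[1:]:
            if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
                raise ValueError("channels of one junction must share the position grid")
        if not self.length > 0:
            raise ValueError("junction length must be > 0")

    @property
    def length(self) -> float:
        return next(iter(self.profiles.values())).length

    @property
    def channels(self) -> list[str]:
        return list(self.profiles)


@dataclass
class JunctionProfileSet:
    """A collection of junction profiles feeding demographs/colocalization."""

    junctions: list[Junction] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.junctions)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([j.length for j in self.junctions])


@dataclass
class Demograph:
    """Junction x position matrix, rows sorted by junction length ascending.

    Rows are resampled to a common step, centered on the junction midpoint and
    NaN-padded; NaNs are excluded from column statistics.
    """

    data: np.ndarray
    positions: np.ndarray      # um, relative to junction midpoint
    lengths: np.ndarray        # sorted junction lengths
    row_order: np.ndarray      # permutation of input indices

    def column_mean(self) -> np.ndarray:
        return np.nanmean(self.data, axis=0)


def demograph(junctions: JunctionProfileSet, channel: str | None = None) -> Demograph:
    """Assemble a demograph for one channel of a junction collection.

    Profiles are resampled to the smallest input step, aligned at their
    midpoints, padded with NaN, and sorted ascending by junction length
    (stable: ties keep input order).
    """
    if len(junctions) < 1:
        raise ValueError("need at least one junction")
    entries = []
    for j in junctions.junctions:
        ch = channel if channel is not None else j.channels[0]
        if ch not in j.profiles:
            raise KeyError(f"junction lacks channel {ch!r}")
        entries.append(j.profiles[ch])
    step = min(p.step for p in entries)
    half = max(p.length for p in entries) / 2
    n_half = int(np.ceil(half / step))
    pos = np.arange(-n_half, n_half + 1) * step
    order = np.argsort([p.length for p in entries], kind="stable")
    rows = []
    for i in order:
        p = entries[i]
        mid = (p.s[0] + p.s[-1]) / 2
        rel = p.s - mid
        row = np.interp(pos, rel, p.intensity, left=np.nan, right=np.nan)
        row[(pos < rel[0] - 1e-12) | (pos > rel[-1] + 1e-12)] = np.nan
        rows.append(row)
    return Demograph(np.stack(rows), pos,
                     np.array([entries[i].length for i in order]),
                     np.asarray(order))
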