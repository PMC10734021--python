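"""Linking localizations into tracks and accumulating super-resolved maps.

Bubbles are linked between consecutive frames by mutual nearest-neighbour
pairing in ascending distance order (the minimum-distance rule), gated by a
maximum link distance.  Tracks must span strictly consecutive frames; tracks
persisting for more than a minimum number of frames (default 10, strict)
enter the velocity statistics.  Per-step speeds are Euclidean displacements
times the frame rate; steps are painted onto the upsampled grid to build
density and velocity maps and cross-channel velocity profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import line as _bresenham_line

__all__ = [
    "Track",
    "DensityMap",
    "VelocityMap",
    "link_tracks",
    "filter_tracks",
    "compute_velocities",
    "accumulate_maps",
    "velocity_profile",
    "tracks_to_frame",
]


@dataclass
class Track:
    """An ordered chain of localizations over strictly consecutive frames."""

    id: int
    frames: list[int] = field(default_factory=list)
    rows: list[float] = field(default_factory=list)
    cols: list[float] = field(default_factory=list)
    x_mm: list[float] = field(default_factory=list)
    z_mm: list[float] = field(default_factory=list)
    step_speeds_mm_s: list[float] | None = None

    def __len__(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        if np.any(np.diff(self.frames) != 1):
            raise ValueError(f"track {self.id}: frame indices not consecutive")


@dataclass
class DensityMap:
    """Localization counts per upsampled grid cell."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class VelocityMap:
    """Mean track-step speed (mm/s) per upsampled grid cell; NaN where empty."""

    speeds: np.ndarray
    n_steps: np.ndarray


def link_tracks(
    localizations: pd.DataFrame, max_link_distance: float
) -> list[Track]:
    """Greedy mutual-nearest linking of localizations across frames.

    For each consecutive frame pair, all candidate pairs within
    ``max_link_distance`` (upsampled pixels) are sorted by distance and
    accepted greedily while both members are unmatched; ties are broken by
    table order, so the result is deterministic.  Unmatched localizations
    start new tracks.  Only tracks whose last localization is in frame ``t``
    can be extended into frame ``t + 1`` (no gap closing).
    """
    if max_link_distance <= 0:
        raise ValueError("max_link_distance must be positive")
    if localizations.empty:
        return []
    loc = localizations.sort_values(["frame", "row", "col"], kind="stable")
    tracks: list[Track] = []
    # active: list of (track, row, col) of tracks ending at the previous frame
    active: list[tuple[Track, float, float, float, float]] = []
    next_id = 0
    prev_frame = None
    for frame, group in loc.groupby("frame", sort=True):
        pts = group[["row", "col", "x_mm", "z_mm"]].to_numpy(float)
        if prev_frame is None or frame != prev_frame + 1 or not active:
            matched_new = np.zeros(len(pts), bool)
            pairs: list[tuple[int, int]] = []
        else:
            a = np.array([[t[1], t[2]] for t in active])
            d = np.sqrt(((a[:, None, :] - pts[None, :, :2]) ** 2).sum(-1))
            ii, jj = np.nonzero(d <= max_link_distance)
            order = np.lexsort((jj, ii, d[ii, jj]))
            used_a = np.zeros(len(active), bool)
            matched_new = np.zeros(len(pts), bool)
            pairs = []
            for k in order:
                i, j = int(ii[k]), int(jj[k])
                if used_a[i] or matched_new[j]:
                    continue
                used_a[i] = True
                matched_new[j] = True
                pairs.append((i, j))
        new_active: list[tuple[Track, float, float, float, float]] = []
        for i, j in pairs:
            t = active[i][0]
            t.frames.append(int(frame))
            t.rows.append(pts[j, 0])
            t.cols.append(pts[j, 1])
            t.x_mm.append(pts[j, 2])
            t.z_mm.append(pts[j, 3])
            new_active.append((t, pts[j, 0], pts[j, 1], pts[j, 2], pts[j, 3]))
        for j in np.nonzero(~matched_new)[0]:
            t = Track(
                id=next_id,
                frames=[int(frame)],
                rows=[pts[j, 0]],
                cols=[pts[j, 1]],
                x_mm=[pts[j, 2]],
                z_mm=[pts[j, 3]],
            )
            next_id += 1
            tracks.append(t)
            new_active.append((t, pts[j, 0], pts[j, 1], pts[j, 2], pts[j, 3]))
        active = new_active
        prev_frame = frame
    return tracks


def filter_tracks(tracks: list[Track], min_frames: int = 10) -> list[Track]:
    """Keep tracks followed for *more than* ``min_frames`` consecutive frames.

    The inequality is strict: with the default of 10, a track needs at least
    11 localizations to survive.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    return [t for t in tracks if len(t) > min_frames]


def compute_velocities(
    track: Track, frame_rate_hz: float, pixel_pitch_mm: float | None = None
) -> np.ndarray:
    """Per-step speeds (mm/s): Euclidean displacement times the frame rate.

    Physical coordinates are used when the track carries them; otherwise
    grid displacements are scaled by ``pixel_pitch_mm`` (the upsampled
    pitch).  The speeds are stored on the track and returned.
    """
    track.validate()
    if track.x_mm and track.z_mm:
        dx = np.diff(track.x_mm)
        dz = np.diff(track.z_mm)
        disp_mm = np.hypot(dx, dz)
    else:
        if pixel_pitch_mm is None:
            raise ValueError("pixel_pitch_mm required for pixel-only tracks")
        disp_mm = np.hypot(np.diff(track.rows), np.diff(track.cols)) * pixel_pitch_mm
    speeds = disp_mm * frame_rate_hz
    track.step_speeds_mm_s = list(speeds)
    return speeds


def accumulate_maps(
    tracks: list[Track], grid_shape: tuple[int, int]
) -> tuple[DensityMap, VelocityMap]:
    """Build super-resolved density and velocity maps from filtered tracks.

    Every localization increments its (rounded) density cell.  Every step's
    speed is painted onto all cells its segment crosses (Bresenham line) and
    each velocity cell becomes the mean of the speeds that touched it.
    Tracks must already carry step speeds (see :func:`compute_velocities`).
    """
    rows, cols = grid_shape
    counts = np.zeros(grid_shape, np.int64)
    speed_sum = np.zeros(grid_shape, float)
    n_steps = np.zeros(grid_shape, np.int64)
    for t in tracks:
        rr = np.clip(np.rint(t.rows).astype(int), 0, rows - 1)
        cc = np.clip(np.rint(t.cols).astype(int), 0, cols - 1)
        np.add.at(counts, (rr, cc), 1)
        if len(t) < 2:
            continue
        if t.step_speeds_mm_s is None:
            raise ValueError(f"track {t.id}: run compute_velocities first")
        for k, speed in enumerate(t.step_speeds_mm_s):
            lr, lc = _bresenham_line(rr[k], cc[k], rr[k + 1], cc[k + 1])
            speed_sum[lr, lc] += speed
            n_steps[lr, lc] += 1
    with np.errstate(invalid="ignore"):
        speeds = np.where(n_steps > 0, speed_sum / np.maximum(n_steps, 1), np.nan)
    return DensityMap(counts=counts), VelocityMap(speeds=speeds, n_steps=n_steps)


def velocity_profile(
    vmap: VelocityMap,
    segment,
    pixel_pitch_mm: float,
    origin_mm: tuple[float, float],
    center_axial_mm: float | None = None,
    n_sections: int = 25,
) -> pd.DataFrame:
    """Cross-channel velocity profile averaged over successive sections.

    ``n_sections`` cross sections perpendicular to the segment axis, one
    pixel pitch apart and centred at ``center_axial_mm`` (segment midpoint
    by default), are sampled from the velocity map at one-pitch lateral
    bins spanning the channel width; NaN cells are ignored in the average.
    Returns a DataFrame with ``lateral_mm`` (signed offset from the axis)
    and ``speed_mm_s``.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    grid = vmap.speeds
    a = np.asarray(segment.start, float)
    d = segment.direction
    n = segment.normal
    half_w = segment.width_um * 1e-3 / 2.0
    if center_axial_mm is None:
        center_axial_mm = segment.length_mm / 2.0
    ax = center_axial_mm + (np.arange(n_sections) - (n_sections - 1) / 2.0) * pixel_pitch_mm
    n_lat = max(int(np.ceil(2 * half_w / pixel_pitch_mm)) | 1, 3)
    lat = (np.arange(n_lat) - (n_lat - 1) / 2.0) * pixel_pitch_mm
    x0, z0 = origin_mm
    pts = (
        a[None, None, :]
        + ax[:, None, None] * d[None, None, :]
        + lat[None, :, None] * n[None, None, :]
    )
    rr = np.rint((pts[..., 1] - z0) / pixel_pitch_mm - 0.5).astype(int)
    cc = np.rint((pts[..., 0] - x0) / pixel_pitch_mm - 0.5).astype(int)
    inside = (
        (rr >= 0) & (rr < grid.shape[0]) & (cc >= 0) & (cc < grid.shape[1])
    )
    if not inside.any():
        raise ValueError("segment does not cross the velocity map")
    vals = np.full(rr.shape, np.nan)
    vals[inside] = grid[rr[inside], cc[inside]]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN lateral bins
        profile = np.nanmean(vals, axis=0)
    return pd.DataFrame({"lateral_mm": lat, "speed_mm_s": profile})


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks into a long table (track_id, frame, positions, speed)."""
    rows = []
    for t in tracks:
        speeds = t.step_speeds_mm_s or [np.nan] * max(len(t) - 1, 0)
        for k in range(len(t)):
            step = speeds[k] if k < len(speeds) else np.nan
            rows.append(
                (t.id, t.frames[k], t.rows[k], t.cols[k], t.x_mm[k], t.z_mm[k], step)
            )
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "row", "col", "x_mm", "z_mm", "speed_mm_s"]
    )
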