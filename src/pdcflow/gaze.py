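"""Normative-gaze Proximity Index.

Per film frame, a Gaussian kernel-density estimate over the reference
(typically developing) group's gaze points defines the normative gaze
distribution. A test subject's frame index is the density at their gaze
point normalised by the frame's density maximum — 1 at the normative
mode, approaching 0 far from all reference gaze — and the Proximity
Index is the mean over usable frames (equivalently the frame-weighted
mean of per-film means). Max-normalisation makes frames with tight and
diffuse reference clouds contribute on a common 0-1 scale.

Bandwidth is Scott's rule per axis (sigma * n^(-1/6)) with a floor of
0.01 screen units; the grid is 64 x 64 over the unit screen by default.
Frames with fewer than 3 valid reference points are unusable for all
subjects; a subject's invalid or off-screen samples skip the frame
rather than scoring zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GazeDataset


class FrameUnusableError(ValueError):
    """Fewer than the minimum number of valid reference points."""


class InsufficientGazeError(RuntimeError):
    def __init__(self, subject: int, used: int, available: int):
        self.subject, self.used, self.available = subject, used, available
        super().__init__(
            f"subject {subject}: valid gaze in {used}/{available} usable frames, "
            "below the minimum fraction"
        )


@dataclass
class DensityMap:
    """KDE of one frame's reference gaze on a regular [0,1]^2 lattice."""

    values: np.ndarray  # (grid, grid), cell-centre evaluations
    bandwidth: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("density must be non-negative")

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    def integral(self) -> float:
        cell = 1.0 / self.grid_size
        return float(self.values.sum() * cell * cell)

    def interpolate(self, x: float, y: float) -> float:
        """Bilinear interpolation at a screen point (cell-centre lattice)."""
        g = self.grid_size
        # cell centres at (k + 0.5)/g
        fx = np.clip(x * g - 0.5, 0.0, g - 1.0)
        fy = np.clip(y * g - 0.5, 0.0, g - 1.0)
        x0, y0 = int(np.floor(fx)), int(np.floor(fy))
        x1, y1 = min(x0 + 1, g - 1), min(y0 + 1, g - 1)
        wx, wy = fx - x0, fy - y0
        v = self.values
        return float(
            v[x0, y0] * (1 - wx) * (1 - wy)
            + v[x1, y0] * wx * (1 - wy)
            + v[x0, y1] * (1 - wx) * wy
            + v[x1, y1] * wx * wy
        )


@dataclass
class ProximityIndex:
    subject_id: str
    value: float
    n_frames_used: int
    per_film_values: dict[int, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError("Proximity Index must lie in [0, 1]")


def _scott_bandwidth(pts: np.ndarray, floor: float = 0.01) -> tuple[float, float]:
    n = len(pts)
    sd = pts.std(axis=0, ddof=1)
    h = sd * n ** (-1.0 / 6.0)
    return (max(float(h[0]), floor), max(float(h[1]), floor))


def kde_frame(
    points: np.ndarray,
    grid_size: int = 64,
    bandwidth: tuple[float, float] | None = None,
    min_points: int = 3,
) -> DensityMap:
    """Gaussian KDE of one frame's valid reference gaze points.

    ``points`` is (n, 2) or (n, 3) with a validity column. Normalised so
    the lattice sum times the cell area is 1 (mass outside the screen is
    folded in by the renormalisation).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise ValueError("points must be (n, 2) or (n, 3)")
    if pts.shape[1] == 3:
        pts = pts[pts[:, 2] > 0.5, :2]
    if len(pts) < min_points:
        raise FrameUnusableError(
            f"{len(pts)} valid reference points (< {min_points})"
        )
    hx, hy = bandwidth if bandwidth is not None else _scott_bandwidth(pts)
    centres = (np.arange(grid_size) + 0.5) / grid_size
    dx = (centres[:, None] - pts[None, :, 0]) / hx  # (g, n)
    dy = (centres[:, None] - pts[None, :, 1]) / hy
    gx = np.exp(-0.5 * dx**2)
    gy = np.exp(-0.5 * dy**2)
    dens = gx @ gy.T  # (g, g): sum_i gx[xi] gy[yi]
    cell = 1.0 / grid_size
    total = dens.sum() * cell * cell
    if total <= 0:
        raise FrameUnusableError("degenerate density (zero mass on screen)")
    return DensityMap(values=dens / total, bandwidth=(hx, hy))


def frame_deviation_index(density: DensityMap, gaze_xy) -> float:
    """Density at the gaze point over the frame's maximum density."""
    x, y = float(gaze_xy[0]), float(gaze_xy[1])
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise ValueError("gaze point is off-screen; the frame should be skipped")
    peak = float(density.values.max())
    if peak <= 0:
        raise ValueError("density map has no mass")
    return min(density.interpolate(x, y) / peak, 1.0)


def proximity_index(
    dataset: GazeDataset,
    subject: int,
    grid_size: int = 64,
    min_ref_points: int = 3,
    min_valid_frac: float = 0.1,
    ref_exclude: int | None = None,
    track: np.ndarray | None = None,
) -> ProximityIndex:
    """Mean per-frame normative-density index for one test subject.

    ``ref_exclude`` drops one reference subject (leave-one-out scoring of
    reference members, whose track is then passed via ``track``).
    ``track`` overrides the subject's stored gaze (n_frames, 3). The
    overall value is the mean over all used frames, which equals the
    frame-weighted mean of the per-film values also reported.
    """
    if track is None:
        track = dataset.test_tracks[subject]
    track = np.asarray(track, dtype=float)
    per_frame: list[tuple[int, float]] = []
    n_usable = 0
    for f in range(dataset.n_frames):
        ref = dataset.reference[f]
        if ref_exclude is not None:
            ref = np.delete(ref, ref_exclude, axis=0)
        try:
            dens = kde_frame(ref, grid_size=grid_size, min_points=min_ref_points)
        except FrameUnusableError:
            continue
        n_usable += 1
        x, y, valid = track[f]
        if valid < 0.5 or not (0 <= x <= 1 and 0 <= y <= 1):
            continue
        per_frame.append((int(dataset.film_ids[f]), frame_deviation_index(dens, (x, y))))
    if n_usable == 0 or len(per_frame) < min_valid_frac * n_usable:
        raise InsufficientGazeError(subject, len(per_frame), n_usable)
    films = sorted({f for f, _ in per_frame})
    per_film = {
        f: float(np.mean([v for g, v in per_frame if g == f])) for f in films
    }
    value = float(np.mean([v for _, v in per_frame]))
    return ProximityIndex(
        subject_id=f"T{subject:03d}",
        value=value,
        n_frames_used=len(per_frame),
        per_film_values=per_film,
    )
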