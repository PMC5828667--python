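"""In-memory containers shared across pipeline stages.

Arrays follow the convention (channels/regions, samples, epochs); a
continuous recording is an epochs array with a single epoch. Each container
carries the metadata the next stage needs (sampling rate, labels,
positions) plus a `history` list recording the operations applied, in
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


def _as_3d(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D array, got shape {data.shape}")
    return data


@dataclass
class SensorEpochs:
    """Scalp EEG: (n_channels, n_samples, n_epochs), microvolt scale."""

    data: np.ndarray
    fs: float
    ch_names: list[str]
    ch_positions: np.ndarray | None = None  # (n_channels, 3), unit sphere
    reference: str = "vertex"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = _as_3d(self.data)
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} channel names for {self.data.shape[0]} rows"
            )
        if self.ch_positions is not None:
            self.ch_positions = np.asarray(self.ch_positions, dtype=float)
            if self.ch_positions.shape != (self.data.shape[0], 3):
                raise ValueError("channel positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sensor data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    @property
    def montage_size(self) -> int:
        return self.n_channels

    def copy_with(self, **kw) -> "SensorEpochs":
        out = replace(self, **kw)
        out.history = list(kw.get("history", self.history))
        return out


@dataclass
class SourceEpochs:
    """Scalar source activity per region: (n_rois, n_samples, n_epochs)."""

    data: np.ndarray
    fs: float
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.data = _as_3d(self.data)
        if len(self.roi_labels) != self.data.shape[0]:
            raise ValueError("roi_labels length must match data rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("source data contains non-finite values")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]


@dataclass
class ROITimeSeries:
    """Region scalar series plus the dipole orientation used to obtain them."""

    data: np.ndarray  # (n_rois, n_samples, n_epochs)
    fs: float
    roi_labels: list[str]
    orientations: np.ndarray  # (n_rois, 3), unit norm

    def __post_init__(self) -> None:
        self.data = _as_3d(self.data)
        self.orientations = np.asarray(self.orientations, dtype=float)
        n = self.data.shape[0]
        if self.orientations.shape != (n, 3):
            raise ValueError("orientations must be (n_rois, 3)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("orientations must be unit-norm")
        if len(self.roi_labels) != n:
            raise ValueError("roi_labels length must match data rows")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]


@dataclass
class Leadfield:
    """Forward gain: potential at each electrode per unit dipole moment.

    gain[e, q, k] is the potential at electrode e from a unit dipole along
    Cartesian axis k at solution point q. Electrodes sit on the unit
    sphere; solution points strictly inside it.
    """

    gain: np.ndarray  # (n_electrodes, n_points, 3)
    electrode_positions: np.ndarray  # (n_electrodes, 3)
    point_positions: np.ndarray  # (n_points, 3)
    point_neighbors: np.ndarray  # (n_points, n_points) symmetric 0/1 adjacency

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.electrode_positions = np.asarray(self.electrode_positions, dtype=float)
        self.point_positions = np.asarray(self.point_positions, dtype=float)
        self.point_neighbors = np.asarray(self.point_neighbors)
        ne, npt, three = self.gain.shape
        if three != 3:
            raise ValueError("gain must be (n_electrodes, n_points, 3)")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain contains non-finite values")
        if np.any(np.all(self.gain.reshape(ne, -1) == 0.0, axis=1)):
            raise ValueError("leadfield has an all-zero electrode row")
        if not np.array_equal(self.point_neighbors, self.point_neighbors.T):
            raise ValueError("point_neighbors must be symmetric")

    @property
    def n_electrodes(self) -> int:
        return self.gain.shape[0]

    @property
    def n_points(self) -> int:
        return self.gain.shape[1]


@dataclass
class SourcePlacement:
    """ROI -> solution point assignment with a fixed dipole orientation."""

    point_indices: np.ndarray  # (n_rois,) into the leadfield point list
    orientations: np.ndarray  # (n_rois, 3) unit vectors

    def __post_init__(self) -> None:
        self.point_indices = np.asarray(self.point_indices, dtype=int)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if len(np.unique(self.point_indices)) != len(self.point_indices):
            raise ValueError("each ROI must map to a distinct solution point")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("placement orientations must be unit-norm")

    @property
    def n_rois(self) -> int:
        return len(self.point_indices)


@dataclass
class GazeDataset:
    """Per-frame reference gaze clouds and per-test-subject gaze tracks.

    Screen coordinates are normalised to [0, 1]^2, origin top-left.
    ``reference`` has shape (n_frames, n_reference, 3) with columns
    (x, y, valid) and ``test_tracks`` (n_test, n_frames, 3) likewise.
    """

    reference: np.ndarray
    test_tracks: np.ndarray
    frame_rate: float
    film_ids: np.ndarray  # (n_frames,) integer film membership

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.test_tracks = np.asarray(self.test_tracks, dtype=float)
        self.film_ids = np.asarray(self.film_ids, dtype=int)
        if self.reference.ndim != 3 or self.reference.shape[2] != 3:
            raise ValueError("reference must be (n_frames, n_reference, 3)")
        if self.test_tracks.ndim != 3 or self.test_tracks.shape[2] != 3:
            raise ValueError("test_tracks must be (n_test, n_frames, 3)")
        if self.test_tracks.shape[1] != self.reference.shape[0]:
            raise ValueError("test_tracks and reference disagree on n_frames")
        if len(self.film_ids) != self.reference.shape[0]:
            raise ValueError("film_ids length must equal n_frames")
        for arr in (self.reference, self.test_tracks):
            valid = arr[..., 2] > 0.5
            xy = arr[..., :2][valid]
            if xy.size and ((xy < 0.0).any() or (xy > 1.0).any()):
                raise ValueError("valid gaze points must lie in [0,1]^2")

    @property
    def n_frames(self) -> int:
        return self.reference.shape[0]

    @property
    def n_reference(self) -> int:
        return self.reference.shape[1]

    @property
    def n_test(self) -> int:
        return self.test_tracks.shape[0]
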