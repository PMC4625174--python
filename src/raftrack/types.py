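"""Core data containers shared across the pipeline.

Coordinates are 0-based pixels with the origin at the top-left corner;
``row`` increases downward, ``col`` to the right.  Physical calibration
(pixel size in µm, frame interval in s) travels with the :class:`Movie`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Spot:
    """A sub-pixel point detection in a single frame.

    ``intensity`` is the summed background-corrected intensity of the
    detection (wavelet detail-plane mass for detected spots, nominal peak
    amplitude for simulated ground-truth spots).
    """

    frame: int
    row_px: float
    col_px: float
    intensity: float
    id: int


@dataclass
class Track:
    """A gap-free trajectory: spots in strictly consecutive frames."""

    track_id: int
    spots: list[Spot]

    def __post_init__(self) -> None:
        if not self.spots:
            raise ValueError("a Track needs at least one spot")
        frames = [s.frame for s in self.spots]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)

    @property
    def positions_px(self) -> np.ndarray:
        """(n, 2) array of (row, col) pixel coordinates."""
        return np.array([(s.row_px, s.col_px) for s in self.spots], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        track_id: int,
        frames,
        rows,
        cols,
        intensities=None,
        ids=None,
    ) -> "Track":
        frames = np.asarray(frames, dtype=int)
        n = len(frames)
        if intensities is None:
            intensities = np.ones(n)
        if ids is None:
            ids = np.full(n, track_id, dtype=int)
        spots = [
            Spot(int(f), float(r), float(c), float(i), int(sid))
            for f, r, c, i, sid in zip(frames, rows, cols, intensities, ids)
        ]
        return cls(track_id, spots)


@dataclass(frozen=True)
class Domain:
    """A segmented connected region in one frame.

    ``mean_intensity`` is measured on the background-subtracted image, not
    on the contrast-enhanced image used to draw the mask.
    """

    label: int
    frame: int
    area_px: int
    area_um2: float
    mean_intensity: float
    centroid_row_px: float
    centroid_col_px: float
    cell_id: int | None = None


@dataclass
class Movie:
    """A T×H×W intensity stack with physical calibration."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("movie data must be T×H×W")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class GroundTruth:
    """Truth channel emitted by the simulator for parameter-recovery tests."""

    true_tracks: list[Track]
    cluster_assignments: dict[int, int] = field(default_factory=dict)
    domain_label_stack: np.ndarray | None = None
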