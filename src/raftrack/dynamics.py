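"""Per-track mobility statistics: speed and the rho linearity ratio.

*rho* is the head-to-tail (first point to end point) distance of a
trajectory divided by the total distance travelled: close to 1 for a
linearly moving spot, close to 0 for confined or random motion.  Speeds
are mean frame-to-frame step distances converted to µm/min.  Before the
linearity analysis, stationary areas are excluded by keeping only spots
that moved a pixel per frame on average or more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Track

__all__ = [
    "TrackMetrics",
    "step_displacements",
    "mean_speed",
    "rho",
    "stationary_filter",
    "compute_track_metrics",
    "metrics_table",
    "summarize_condition",
]


@dataclass(frozen=True)
class TrackMetrics:
    track_id: int
    n_frames: int
    mean_step_px: float
    mean_speed_um_min: float
    net_displacement_um: float
    path_length_um: float
    rho: float


def step_displacements(track: Track) -> np.ndarray:
    """Euclidean distances between consecutive spots, in px."""
    if len(track) < 2:
        raise ValueError("track must have at least 2 points")
    pos = track.positions_px
    return np.linalg.norm(np.diff(pos, axis=0), axis=1)


def mean_speed(track: Track, pixel_size_um: float, frame_interval_s: float) -> float:
    """Mean frame-to-frame speed in µm/min."""
    if pixel_size_um <= 0 or frame_interval_s <= 0:
        raise ValueError("calibration must be positive")
    steps = step_displacements(track)
    return float(steps.mean() * pixel_size_um / (frame_interval_s / 60.0))


def rho(track: Track) -> float:
    """Head-to-tail distance over total path length, in [0, 1]."""
    steps = step_displacements(track)
    path = float(steps.sum())
    if path == 0.0:
        raise ValueError("rho is undefined for a zero-path track")
    pos = track.positions_px
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    # triangle inequality guarantees net <= path; clip float crumbs
    return min(net / path, 1.0)


def stationary_filter(tracks: list[Track], min_mean_step_px: float = 1.0) -> list[Track]:
    """Exclude stationary areas: keep tracks whose mean step is at least
    ``min_mean_step_px`` px/frame (boundary inclusive)."""
    kept = []
    for t in tracks:
        if len(t) < 2:
            continue
        if float(step_displacements(t).mean()) >= min_mean_step_px:
            kept.append(t)
    return kept


def compute_track_metrics(
    track: Track, pixel_size_um: float, frame_interval_s: float
) -> TrackMetrics:
    """All mobility metrics for one track.

    ``rho`` is NaN for zero-path tracks (such tracks are excluded by the
    stationary filter before any linearity analysis).
    """
    steps = step_displacements(track)
    pos = track.positions_px
    net_px = float(np.linalg.norm(pos[-1] - pos[0]))
    path_px = float(steps.sum())
    return TrackMetrics(
        track_id=track.track_id,
        n_frames=len(track),
        mean_step_px=float(steps.mean()),
        mean_speed_um_min=mean_speed(track, pixel_size_um, frame_interval_s),
        net_displacement_um=net_px * pixel_size_um,
        path_length_um=path_px * pixel_size_um,
        rho=min(net_px / path_px, 1.0) if path_px > 0 else float("nan"),
    )


def metrics_table(
    tracks: list[Track],
    pixel_size_um: float,
    frame_interval_s: float,
    min_mean_step_px: float = 1.0,
) -> pd.DataFrame:
    """Tidy per-track metric table with a ``stationary`` flag column."""
    rows = []
    for t in tracks:
        if len(t) < 2:
            continue
        m = compute_track_metrics(t, pixel_size_um, frame_interval_s)
        rows.append({
            "track_id": m.track_id,
            "n_frames": m.n_frames,
            "mean_step_px": m.mean_step_px,
            "mean_speed_um_min": m.mean_speed_um_min,
            "net_displacement_um": m.net_displacement_um,
            "path_length_um": m.path_length_um,
            "rho": m.rho,
            "stationary": m.mean_step_px < min_mean_step_px,
        })
    return pd.DataFrame(rows, columns=[
        "track_id", "n_frames", "mean_step_px", "mean_speed_um_min",
        "net_displacement_um", "path_length_um", "rho", "stationary",
    ])


def summarize_condition(values) -> dict[str, float]:
    """Box-plot summary: median, quartiles, 10th/90th percentiles, mean, n.

    Order statistics use linear interpolation between closest ranks (the
    numpy default); the convention is recorded here because box-plot
    conventions differ between tools.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q = np.percentile(values, [10, 25, 50, 75, 90])
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "p10": float(q[0]),
        "q25": float(q[1]),
        "median": float(q[2]),
        "q75": float(q[3]),
        "p90": float(q[4]),
    }
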