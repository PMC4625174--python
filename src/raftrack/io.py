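"""TIFF and CSV input/output for movies, tracks, spots and domains."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import Movie, Spot, Track

__all__ = [
    "write_movie_tiff",
    "read_movie_tiff",
    "write_label_stack_tiff",
    "tracks_to_frame",
    "write_tracks_csv",
    "read_tracks_csv",
]


def write_movie_tiff(movie: Movie, path: str | Path) -> None:
    """Write a movie as a multi-page 16-bit grayscale TIFF."""
    data = np.clip(np.asarray(movie.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        metadata={
            "axes": "TYX",
            "pixel_size_um": movie.pixel_size_um,
            "frame_interval_s": movie.frame_interval_s,
        },
    )


def read_movie_tiff(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> Movie:
    """Read a T×H×W TIFF stack; calibration from metadata unless overridden."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise ValueError(
            "pixel_size_um and frame_interval_s must come from TIFF metadata "
            "or be supplied explicitly"
        )
    return Movie(data, float(px), float(dt))


def write_label_stack_tiff(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.int32), metadata={"axes": "TYX"})


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        {"track_id": t.track_id, "frame": s.frame, "spot_id": s.id,
         "row_px": s.row_px, "col_px": s.col_px, "intensity": s.intensity}
        for t in tracks
        for s in t.spots
    ]
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "spot_id", "row_px", "col_px", "intensity"]
    )


def write_tracks_csv(tracks: list[Track], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        tracks.append(
            Track.from_arrays(
                int(tid),
                frames=grp["frame"].to_numpy(int),
                rows=grp["row_px"].to_numpy(float),
                cols=grp["col_px"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float)
                if "intensity" in grp else None,
                ids=grp["spot_id"].to_numpy(int) if "spot_id" in grp else None,
            )
        )
    return tracks
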