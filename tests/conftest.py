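import numpy as np
import pytest

from raftrack import LinkParams, SegmentationParams, SimConfig, WaveletParams
from raftrack.types import Spot, Track


@pytest.fixture
def default_sim() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture
def seg_params() -> SegmentationParams:
    # manual threshold chosen for the default-SNR synthetic movies
    return SegmentationParams(threshold=70.0)


@pytest.fixture
def wavelet_params() -> WaveletParams:
    return WaveletParams()


@pytest.fixture
def link_params() -> LinkParams:
    return LinkParams()


def make_track(coords, track_id: int = 0, start_frame: int = 0) -> Track:
    """Track from a list of (row, col) pixel coordinates."""
    coords = np.asarray(coords, dtype=float)
    return Track.from_arrays(
        track_id,
        frames=np.arange(start_frame, start_frame + len(coords)),
        rows=coords[:, 0],
        cols=coords[:, 1],
    )


def make_spots(frame: int, coords) -> list[Spot]:
    return [
        Spot(frame=frame, row_px=float(r), col_px=float(c), intensity=1.0, id=i)
        for i, (r, c) in enumerate(coords)
    ]
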