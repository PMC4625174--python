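"""Ground-truthed synthetic time-lapse movies of punctate membrane domains.

Two motion regimes are generated:

* **brownian** — every spot performs free 2-D Brownian motion with
  diffusion coefficient D (per-axis steps ~ Normal(0, sqrt(2·D·Δt)) in µm),
  reflected at the field borders.  This emulates untreated receptor domains
  diffusing in the membrane.
* **clustered** — a configurable fraction of spots is attracted to the
  nearest of a few cluster centers and, once within the capture radius,
  rides rigidly on that center.  Centers wobble inside a reflecting
  confinement radius, so captured domains keep moving — slowly and with low
  net displacement — the way ligand-arrested receptor clusters do.  The
  remaining spots diffuse freely.

Rendering places an isotropic Gaussian PSF at each spot position, adds a
constant background, then Poisson shot noise and Gaussian read noise, and
clips to 16 bit.  Defaults give a peak signal-to-background-noise ratio of
about 8.  Ground truth (continuous tracks, cluster assignments, and label
images of the noiseless ≥50 %-of-peak regions) accompanies every movie.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import SimConfig
from .types import GroundTruth, Movie, Spot, Track

__all__ = [
    "simulate_brownian_tracks",
    "simulate_clustered_tracks",
    "render_movie",
    "simulate_movie",
    "simulate_efflux_counts",
    "grid_cell_mask",
]


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by mirror reflection at both walls."""
    if hi <= lo:
        raise ValueError("empty reflection interval")
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def _step_sd_px(cfg: SimConfig) -> float:
    # per-axis Brownian step sd in px: sqrt(2 D dt) µm converted to px
    return np.sqrt(2.0 * cfg.diffusion_um2_s * cfg.frame_interval_s) / cfg.pixel_size_um


def _tracks_from_paths(paths: np.ndarray, amplitude: float) -> list[Track]:
    """paths: (n_spots, n_frames, 2) px coordinates -> one Track per spot."""
    n_spots, n_frames, _ = paths.shape
    tracks = []
    for i in range(n_spots):
        tracks.append(
            Track.from_arrays(
                i,
                frames=np.arange(n_frames),
                rows=paths[i, :, 0],
                cols=paths[i, :, 1],
                intensities=np.full(n_frames, amplitude),
                ids=np.full(n_frames, i),
            )
        )
    return tracks


def simulate_brownian_tracks(cfg: SimConfig) -> list[Track]:
    """Free 2-D Brownian tracks, one per spot, reflected at the borders."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height_px, cfg.width_px
    start = rng.uniform([0, 0], [h - 1, w - 1], size=(cfg.n_spots, 2))
    steps = rng.normal(0.0, _step_sd_px(cfg), size=(cfg.n_spots, cfg.n_frames - 1, 2))
    paths = np.concatenate([start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
    paths[..., 0] = _reflect(paths[..., 0], 0.0, h - 1.0)
    paths[..., 1] = _reflect(paths[..., 1], 0.0, w - 1.0)
    return _tracks_from_paths(paths, cfg.spot_amplitude)


def simulate_clustered_tracks(cfg: SimConfig) -> tuple[list[Track], dict[int, int]]:
    """Clustered-condition tracks plus a track_id → cluster-center map.

    Free spots (``1 - cluster_fraction`` of the total) carry assignment -1.
    A burn-in of ``cluster_burn_in_frames`` unrecorded frames lets capture
    reach steady state before frame 0.
    """
    cfg.validate()
    if cfg.cluster_fraction <= 0:
        raise ValueError("cluster_fraction must be > 0 for the clustered condition")
    if cfg.n_cluster_centers >= cfg.n_spots:
        raise ValueError("need fewer cluster centers than spots")
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height_px, cfg.width_px
    px = cfg.pixel_size_um
    capture_r = cfg.cluster_capture_radius_um / px
    attract_step = cfg.cluster_attraction_um_per_frame / px
    jitter_sd = cfg.cluster_center_jitter_um / px
    step_sd = _step_sd_px(cfg)

    n_clustered = int(round(cfg.cluster_fraction * cfg.n_spots))
    n_free = cfg.n_spots - n_clustered

    margin = min(capture_r + 5.0, min(h, w) / 4.0)
    anchors = rng.uniform([margin, margin], [h - 1 - margin, w - 1 - margin],
                          size=(cfg.n_cluster_centers, 2))

    pos = rng.uniform([0, 0], [h - 1, w - 1], size=(cfg.n_spots, 2))
    clustered = np.zeros(cfg.n_spots, dtype=bool)
    clustered[:n_clustered] = True
    # nearest anchor at start; -1 for free spots
    d2 = ((pos[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
    assignment = np.where(clustered, np.argmin(d2, axis=1), -1)

    centers = anchors.copy()
    captured = np.zeros(cfg.n_spots, dtype=bool)
    capture_offset = np.zeros((cfg.n_spots, 2))
    total = cfg.cluster_burn_in_frames + cfg.n_frames
    recorded = np.empty((cfg.n_spots, cfg.n_frames, 2))

    for t in range(total):
        # confined center wobble: reflect within capture radius of the anchor
        if jitter_sd > 0:
            centers = centers + rng.normal(0.0, jitter_sd, size=centers.shape)
            for ax in range(2):
                centers[:, ax] = _reflect(
                    centers[:, ax] - anchors[:, ax], -capture_r, capture_r
                ) + anchors[:, ax]

        # newly captured spots: lock in a small co-localization offset
        if n_clustered:
            tgt = centers[np.clip(assignment, 0, None)]
            dist = np.linalg.norm(pos - tgt, axis=1)
            newly = clustered & ~captured & (dist <= capture_r)
            if newly.any():
                captured |= newly
                capture_offset[newly] = rng.normal(0.0, 0.5, size=(newly.sum(), 2))

        if t >= cfg.cluster_burn_in_frames:
            recorded[:, t - cfg.cluster_burn_in_frames, :] = pos

        if t == total - 1:
            break

        noise = rng.normal(0.0, step_sd, size=(cfg.n_spots, 2))
        new_pos = pos + noise
        if n_clustered:
            tgt = centers[np.clip(assignment, 0, None)]
            vec = tgt - pos
            dist = np.linalg.norm(vec, axis=1)
            drifting = clustered & ~captured & (dist > 1e-9)
            step_len = np.minimum(attract_step, dist)
            drift = np.zeros_like(pos)
            drift[drifting] = (
                vec[drifting] / dist[drifting, None] * step_len[drifting, None]
            )
            new_pos = np.where(drifting[:, None], pos + drift + noise, new_pos)
            new_pos = np.where(captured[:, None], tgt + capture_offset, new_pos)
        new_pos[:, 0] = _reflect(new_pos[:, 0], 0.0, h - 1.0)
        new_pos[:, 1] = _reflect(new_pos[:, 1], 0.0, w - 1.0)
        pos = new_pos

    tracks = _tracks_from_paths(recorded, cfg.spot_amplitude)
    return tracks, {i: int(assignment[i]) for i in range(cfg.n_spots)}


def _paint_gaussians(frame_img: np.ndarray, rows, cols, amps, sigma: float) -> None:
    """Add truncated (±5σ window) Gaussian peaks in place."""
    h, w = frame_img.shape
    half = int(np.ceil(5 * sigma))
    for r0, c0, a in zip(rows, cols, amps):
        rlo, rhi = max(0, int(np.floor(r0)) - half), min(h, int(np.floor(r0)) + half + 1)
        clo, chi = max(0, int(np.floor(c0)) - half), min(w, int(np.floor(c0)) + half + 1)
        if rlo >= rhi or clo >= chi:
            continue
        rr = np.arange(rlo, rhi)[:, None] - r0
        cc = np.arange(clo, chi)[None, :] - c0
        frame_img[rlo:rhi, clo:chi] += a * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def render_movie(
    tracks: list[Track],
    cfg: SimConfig,
    noise: bool = True,
) -> tuple[Movie, GroundTruth]:
    """Render tracks to a 16-bit movie and build the ground-truth channel.

    Spots are isotropic Gaussians of sd ``psf_sigma_px`` and peak
    ``spot_amplitude``; overlapping spots sum.  With ``noise`` the clean
    image receives Poisson shot noise followed by Gaussian read noise.
    The ground-truth label stack marks, per frame, the 8-connected regions
    where the noiseless spot signal reaches at least half the nominal peak.
    """
    from scipy import ndimage

    cfg.validate()
    n_frames = max((int(t.frames.max()) for t in tracks), default=cfg.n_frames - 1) + 1
    h, w = cfg.height_px, cfg.width_px
    rng = np.random.default_rng([cfg.seed, 0xA5])

    data = np.empty((n_frames, h, w), dtype=np.uint16)
    labels = np.zeros((n_frames, h, w), dtype=np.int32)

    by_frame: dict[int, list[Spot]] = {}
    for tr in tracks:
        for s in tr.spots:
            if not (0 <= s.row_px <= h - 1 and 0 <= s.col_px <= w - 1):
                raise ValueError("track coordinates must lie inside image bounds")
            by_frame.setdefault(s.frame, []).append(s)

    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    for t in range(n_frames):
        signal = np.zeros((h, w))
        spots = by_frame.get(t, [])
        if spots:
            _paint_gaussians(
                signal,
                [s.row_px for s in spots],
                [s.col_px for s in spots],
                [s.intensity for s in spots],
                cfg.psf_sigma_px,
            )
        lab, n_lab = ndimage.label(signal >= 0.5 * cfg.spot_amplitude, structure=structure)
        labels[t] = lab
        clean = signal + cfg.background_level
        if noise:
            img = rng.poisson(clean).astype(float)
            img += rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
        else:
            img = clean
        data[t] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    if data.min() >= 65535:
        warnings.warn("rendered movie is fully saturated; check amplitude/background")

    movie = Movie(data, cfg.pixel_size_um, cfg.frame_interval_s)
    truth = GroundTruth(true_tracks=tracks, domain_label_stack=labels)
    return movie, truth


def simulate_movie(cfg: SimConfig, condition: str = "brownian") -> tuple[Movie, GroundTruth]:
    """Simulate tracks for a condition and render them in one call."""
    if condition == "brownian":
        tracks = simulate_brownian_tracks(cfg)
        assignments: dict[int, int] = {}
    elif condition == "clustered":
        tracks, assignments = simulate_clustered_tracks(cfg)
    else:
        raise ValueError("condition must be 'brownian' or 'clustered'")
    movie, truth = render_movie(tracks, cfg)
    truth.cluster_assignments = assignments
    return movie, truth


def simulate_efflux_counts(
    true_fraction: float, total_counts: int, seed: int
) -> tuple[int, int]:
    """Scintillation count pair (media, cells) for a true efflux fraction."""
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must lie in [0, 1]")
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    rng = np.random.default_rng(seed)
    counts_media = int(rng.binomial(total_counts, true_fraction))
    return counts_media, total_counts - counts_media


def grid_cell_mask(height_px: int, width_px: int, n_rows: int = 2, n_cols: int = 2) -> np.ndarray:
    """Tile the field into a grid of pseudo-cells labelled 1..n_rows*n_cols.

    Synthetic movies carry no real cell outlines; a fixed tiling provides
    the per-cell observational unit for domain-count comparisons.
    """
    rows = np.minimum(np.arange(height_px) * n_rows // height_px, n_rows - 1)
    cols = np.minimum(np.arange(width_px) * n_cols // width_px, n_cols - 1)
    return (rows[:, None] * n_cols + cols[None, :] + 1).astype(np.int32)
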