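"""Parameter containers for every pipeline stage, YAML round-trippable."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class SimConfig:
    """Synthetic time-lapse acquisition and motion parameters.

    Defaults emulate the acquisition the pipeline targets: 60-frame movies
    (2 min at a 2 s lapse) of punctate receptor domains.  The pixel size is
    not dictated by the imaging protocol; 0.16 µm/px (typical 100× confocal)
    is the default and every physical threshold downstream is expressed in
    physical units so this choice is not load-bearing.

    Clustered-condition parameters: a ``cluster_fraction`` share of spots is
    attracted to the nearest of ``n_cluster_centers`` at
    ``cluster_attraction_um_per_frame``; once within
    ``cluster_capture_radius_um`` of its center a spot is captured and rides
    on the center, which itself wobbles with per-axis Gaussian steps of sd
    ``cluster_center_jitter_um`` confined (reflecting) within the capture
    radius of its anchor.  ``cluster_burn_in_frames`` of unrecorded pre-roll
    let capture reach steady state before frame 0, emulating imaging long
    after treatment.
    """

    n_frames: int = 60
    frame_interval_s: float = 2.0
    pixel_size_um: float = 0.16
    height_px: int = 128
    width_px: int = 128
    n_spots: int = 40
    diffusion_um2_s: float = 0.01
    cluster_fraction: float = 0.8
    n_cluster_centers: int = 8
    cluster_capture_radius_um: float = 0.5
    cluster_attraction_um_per_frame: float = 0.5
    cluster_center_jitter_um: float = 0.16
    cluster_burn_in_frames: int = 40
    psf_sigma_px: float = 1.3
    spot_amplitude: float = 80.0
    background_level: float = 100.0
    read_noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in (
            "frame_interval_s",
            "pixel_size_um",
            "psf_sigma_px",
            "cluster_capture_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.height_px < 8 or self.width_px < 8:
            raise ValueError("image must be at least 8x8 px")
        if not np.isfinite(self.diffusion_um2_s) or self.diffusion_um2_s < 0:
            raise ValueError("diffusion coefficient must be finite and >= 0")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        if self.spot_amplitude < 0 or self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("intensity parameters must be >= 0")


@dataclass
class SegmentationParams:
    """Domain segmentation: background removal, contrast enhancement, mask.

    ``threshold`` is an intensity value chosen manually (the intended
    workflow) or the string ``"otsu"`` for unattended runs; which was used
    is recorded in output metadata.
    """

    background_radius_px: int = 50
    unsharp_radius_px: float = 25.0
    unsharp_amount: float = 0.9
    threshold: float | str = "otsu"
    min_area_px: int = 4

    def validate(self) -> None:
        if self.background_radius_px < 1 or self.unsharp_radius_px < 1:
            raise ValueError("filter radii must be >= 1 px")
        if not 0 < self.unsharp_amount <= 2:
            raise ValueError("unsharp_amount must lie in (0, 2]")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError("threshold must be a number or 'otsu'")


@dataclass
class WaveletParams:
    """À-trous spot detection: decomposition depth, detection plane, k·σ.

    ``min_component_px`` discards supra-threshold components smaller than a
    diffraction-limited spot at the detection scale: isolated k·σ noise
    exceedances span only 1–5 px after the level-2 smoothing, while a real
    spot's component covers well over 10 px.
    """

    n_levels: int = 3
    detection_level: int = 2
    k_sigma: float = 3.0
    min_component_px: int = 8

    def validate(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if not 1 <= self.detection_level <= self.n_levels:
            raise ValueError("detection_level must lie in [1, n_levels]")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")


@dataclass
class LinkParams:
    """Frame-pair linking under a hard speed cap, no gap closing.

    The 42 µm/min default cap accommodates the fastest motion observed in
    the target data; ``nonlink_cost_factor`` places the birth/death
    alternative marginally above the worst admissible link so that any
    admissible link beats two non-links.
    """

    max_speed_um_min: float = 42.0
    pixel_size_um: float = 0.16
    frame_interval_s: float = 2.0
    nonlink_cost_factor: float = 1.05

    def validate(self) -> None:
        for name in (
            "max_speed_um_min",
            "pixel_size_um",
            "frame_interval_s",
            "nonlink_cost_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DynamicsParams:
    """Track-metric filters.

    ``min_track_frames=5`` keeps tracks lasting over four frames;
    ``min_mean_step_px=1.0`` excludes stationary areas (spots must move a
    pixel per frame on average or more), applied to the linearity (rho)
    analysis by default and optionally to speeds as well.
    """

    min_track_frames: int = 5
    min_mean_step_px: float = 1.0
    stationary_filter_scope: str = "rho"  # "rho" or "both"

    def validate(self) -> None:
        if self.min_track_frames < 1:
            raise ValueError("min_track_frames must be >= 1")
        if self.min_mean_step_px < 0:
            raise ValueError("min_mean_step_px must be >= 0")
        if self.stationary_filter_scope not in ("rho", "both"):
            raise ValueError("stationary_filter_scope must be 'rho' or 'both'")


@dataclass
class StatsParams:
    n_permutations: int = 10000
    two_sided: bool = True

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class ExperimentConfig:
    """Full two-condition experiment: simulation, analysis and test settings.

    Both conditions are analysed with identical parameters; the comparison
    stage enforces this to guard against analysis confounds.
    """

    condition_a: SimConfig = field(default_factory=SimConfig)
    condition_b: SimConfig = field(default_factory=SimConfig)
    condition_a_name: str = "untreated"
    condition_b_name: str = "treated"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    linking: LinkParams = field(default_factory=LinkParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    stats: StatsParams = field(default_factory=StatsParams)
    segment_frames: list[int] | None = None  # None = all frames
    output_dir: str = "raftrack_out"
    seed: int = 0

    def validate(self) -> None:
        for sub in (
            self.condition_a,
            self.condition_b,
            self.segmentation,
            self.wavelet,
            self.linking,
            self.dynamics,
            self.stats,
        ):
            sub.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, typ in (
            ("condition_a", SimConfig),
            ("condition_b", SimConfig),
            ("segmentation", SegmentationParams),
            ("wavelet", WaveletParams),
            ("linking", LinkParams),
            ("dynamics", DynamicsParams),
            ("stats", StatsParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        cfg = cls.from_dict(yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg

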