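"""Two-condition experiment orchestration.

``run_condition`` executes the full analysis chain on one movie —
segmentation morphometrics, wavelet detection, capped LAP linking, track
assembly, lifetime and stationarity filtering, per-track metrics — and
logs row counts at every filtering stage.  ``compare_conditions`` then
permutation-tests the five endpoint sets (domain area, domain brightness,
domains per cell, speed, rho) between two conditions analysed with
identical parameters, returning a :class:`RunReport` with box-plot
summaries and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig
from .detect import detect_movie, spots_to_frame
from .dynamics import metrics_table, summarize_condition
from .linking import build_tracks, lifetime_filter, link_movie
from .segment import domains_per_cell, segment_movie
from .stats import PermutationResult, permutation_test_means
from .synthetic import grid_cell_mask, simulate_movie
from .types import Movie

log = logging.getLogger(__name__)

__all__ = ["ConditionTables", "RunReport", "run_condition", "compare_conditions",
           "run_experiment", "endpoint_samples", "ENDPOINTS"]

ENDPOINTS = ("domain_area", "domain_brightness", "domains_per_cell", "speed", "rho")


@dataclass
class ConditionTables:
    """All tabular outputs of one condition plus filter accounting."""

    name: str
    domains: pd.DataFrame
    spots: pd.DataFrame
    metrics: pd.DataFrame
    domain_counts: pd.DataFrame  # per (frame, cell) domain counts
    stage_counts: dict[str, int]
    analysis_params: dict


@dataclass
class RunReport:
    """Comparison report for the five condition endpoints."""

    condition_a: str
    condition_b: str
    tests: dict[str, PermutationResult]
    summaries: dict[str, dict[str, dict[str, float]]]
    n_rows: dict[str, dict[str, int]]
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def summary(self) -> str:
        lines = [
            f"raftrack {self.version} condition comparison: "
            f"{self.condition_a} vs {self.condition_b}",
            f"{'endpoint':<18}{'n_a':>6}{'n_b':>6}{'median_a':>12}"
            f"{'median_b':>12}{'diff_means':>12}{'p':>10}",
        ]
        for name, res in self.tests.items():
            sa = self.summaries[name][self.condition_a]
            sb = self.summaries[name][self.condition_b]
            lines.append(
                f"{name:<18}{sa['n']:>6}{sb['n']:>6}{sa['median']:>12.4g}"
                f"{sb['median']:>12.4g}{res.observed_diff:>12.4g}{res.p_value:>10.4g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "version": self.version,
            "timestamp": self.timestamp,
            "tests": {k: dataclasses.asdict(v) for k, v in self.tests.items()},
            "summaries": self.summaries,
            "n_rows": self.n_rows,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _analysis_params(cfg: ExperimentConfig) -> dict:
    return {
        "segmentation": dataclasses.asdict(cfg.segmentation),
        "wavelet": dataclasses.asdict(cfg.wavelet),
        "linking": dataclasses.asdict(cfg.linking),
        "dynamics": dataclasses.asdict(cfg.dynamics),
        "segment_frames": cfg.segment_frames,
    }


def run_condition(
    movie: Movie,
    cfg: ExperimentConfig,
    name: str = "condition",
    cell_mask: np.ndarray | None = None,
    out_dir: str | Path | None = None,
) -> ConditionTables:
    """Run segmentation + tracking + dynamics on one movie.

    ``cell_mask`` is a 2-D label image (0 = no cell); when absent, a 2×2
    pseudo-cell tiling of the field provides the per-cell counting unit.
    With ``out_dir``, intermediate CSVs are written alongside the results.
    """
    cfg.validate()
    if cell_mask is None:
        cell_mask = grid_cell_mask(movie.shape[1], movie.shape[2])

    link_params = dataclasses.replace(
        cfg.linking,
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
    )

    domains = segment_movie(movie, cfg.segmentation, frames=cfg.segment_frames,
                            cell_mask=cell_mask)
    count_rows = []
    for frame_idx, grp in domains.groupby("frame"):
        doms = grp.to_dict("records")
        per_cell: dict[int, int] = {int(l): 0 for l in np.unique(cell_mask) if l > 0}
        for d in doms:
            if d["cell_id"] is not None and not pd.isna(d["cell_id"]):
                per_cell[int(d["cell_id"])] += 1
        for cell, cnt in sorted(per_cell.items()):
            count_rows.append({"frame": int(frame_idx), "cell_id": cell, "n_domains": cnt})
    domain_counts = pd.DataFrame(count_rows, columns=["frame", "cell_id", "n_domains"])

    spots_by_frame = detect_movie(movie, cfg.wavelet)
    n_spots = sum(len(s) for s in spots_by_frame)
    links = link_movie(spots_by_frame, link_params)
    n_links = sum(len(l) for l in links)
    tracks = build_tracks(links, spots_by_frame)
    kept = lifetime_filter(tracks, cfg.dynamics.min_track_frames)
    metrics = metrics_table(
        kept, movie.pixel_size_um, movie.frame_interval_s,
        min_mean_step_px=cfg.dynamics.min_mean_step_px,
    )
    n_moving = int((~metrics["stationary"]).sum()) if len(metrics) else 0

    stage_counts = {
        "spots": n_spots,
        "links": n_links,
        "tracks": len(tracks),
        "tracks_lifetime_filtered": len(kept),
        "tracks_nonstationary": n_moving,
    }
    for stage, count in stage_counts.items():
        log.info("%s: %s = %d", name, stage, count)

    tables = ConditionTables(
        name=name,
        domains=domains,
        spots=spots_to_frame(spots_by_frame),
        metrics=metrics,
        domain_counts=domain_counts,
        stage_counts=stage_counts,
        analysis_params=_analysis_params(cfg),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables.domains.to_csv(out / f"{name}_domains.csv", index=False)
        tables.spots.to_csv(out / f"{name}_spots.csv", index=False)
        tables.metrics.to_csv(out / f"{name}_track_metrics.csv", index=False)
        tables.domain_counts.to_csv(out / f"{name}_domain_counts.csv", index=False)
    return tables


def endpoint_samples(t: ConditionTables, scope: str) -> dict[str, np.ndarray]:
    metrics = t.metrics
    moving = metrics[~metrics["stationary"]]
    speed_src = moving if scope == "both" else metrics
    return {
        "domain_area": t.domains["area_um2"].to_numpy(float),
        "domain_brightness": t.domains["mean_intensity"].to_numpy(float),
        "domains_per_cell": t.domain_counts["n_domains"].to_numpy(float),
        "speed": speed_src["mean_speed_um_min"].to_numpy(float),
        "rho": moving["rho"].dropna().to_numpy(float),
    }


def compare_conditions(
    a: ConditionTables, b: ConditionTables, cfg: ExperimentConfig
) -> RunReport:
    """Permutation-test the five endpoints between two conditions.

    Both conditions must have been analysed with identical parameters;
    a mismatch is a confound and is rejected.
    """
    if a.analysis_params != b.analysis_params:
        raise ValueError(
            "conditions were analysed with different parameters; "
            "comparison would be confounded"
        )
    scope = cfg.dynamics.stationary_filter_scope
    sa = endpoint_samples(a, scope)
    sb = endpoint_samples(b, scope)
    tests: dict[str, PermutationResult] = {}
    summaries: dict[str, dict[str, dict[str, float]]] = {}
    n_rows: dict[str, dict[str, int]] = {}
    for i, name in enumerate(ENDPOINTS):
        xa, xb = sa[name], sb[name]
        tests[name] = permutation_test_means(
            xa, xb,
            n_permutations=cfg.stats.n_permutations,
            seed=cfg.seed + i,
            two_sided=cfg.stats.two_sided,
        )
        summaries[name] = {
            a.name: summarize_condition(xa),
            b.name: summarize_condition(xb),
        }
        n_rows[name] = {a.name: int(xa.size), b.name: int(xb.size)}
    return RunReport(a.name, b.name, tests, summaries, n_rows)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> RunReport:
    """Simulate both conditions, analyse each, and compare them.

    Condition A is the untreated (freely diffusing) phenotype, condition B
    the treated (clustered, confined) one.  The resolved configuration is
    written next to the results so every run is reproducible.
    """
    cfg.validate()
    movie_a, _ = simulate_movie(cfg.condition_a, condition="brownian")
    movie_b, _ = simulate_movie(cfg.condition_b, condition="clustered")
    ta = run_condition(movie_a, cfg, name=cfg.condition_a_name, out_dir=out_dir)
    tb = run_condition(movie_b, cfg, name=cfg.condition_b_name, out_dir=out_dir)
    report = compare_conditions(ta, tb, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.save(out / "resolved_config.yaml")
        report.save(out / "report.json")
    return report
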