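"""Frame-to-frame spot linking as an exact linear assignment problem.

The movie-wide "most likely links" optimisation decomposes, when gap
closing is disabled (every track must be gap-free), into independent
assignment problems between consecutive frame pairs: no decision in pair
(t, t+1) constrains pair (t+1, t+2) beyond the spots themselves.  Each
pair is solved exactly with the Jonker–Volgenant solver on the augmented
cost matrix

    ┌────────────┬──────────────┐
    │ d²(a_i,b_j)│ death (diag) │
    ├────────────┼──────────────┤
    │ birth (diag)│ transpose-ok │
    └────────────┴──────────────┘

where a link is admissible only if the implied speed is at most the cap
(42 µm/min by default), its cost is the squared displacement in px² (the
most-likely-links cost under Gaussian motion), and the birth/death
alternative costs ``nonlink_cost_factor`` × cap² so that any admissible
link beats a death plus a birth.  The lower-right block carries zero cost
wherever the corresponding link is admissible, which completes the square
matrix without altering the objective.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import LinkParams
from .types import Spot, Track

__all__ = [
    "max_disp_px",
    "link_frame_pair",
    "link_movie",
    "build_tracks",
    "lifetime_filter",
]


def max_disp_px(params: LinkParams) -> float:
    """Largest admissible per-frame displacement, in pixels."""
    params.validate()
    return params.max_speed_um_min * (params.frame_interval_s / 60.0) / params.pixel_size_um


def _check_unique_ids(spots: list[Spot], which: str) -> None:
    ids = [s.id for s in spots]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate spot ids in {which} frame")


def link_frame_pair(
    spots_a: list[Spot], spots_b: list[Spot], params: LinkParams
) -> list[tuple[int, int]]:
    """Exact minimum-cost links between two consecutive frames.

    Returns ``(id_a, id_b)`` pairs; unlinked spots implicitly die or are
    born.  Ties between equal-cost optima are broken toward the
    lexicographically smallest link set by (id_a, id_b).
    """
    params.validate()
    _check_unique_ids(spots_a, "first")
    _check_unique_ids(spots_b, "second")
    n, m = len(spots_a), len(spots_b)
    if n == 0 or m == 0:
        return []

    a = sorted(spots_a, key=lambda s: s.id)
    b = sorted(spots_b, key=lambda s: s.id)
    pa = np.array([(s.row_px, s.col_px) for s in a])
    pb = np.array([(s.row_px, s.col_px) for s in b])
    maxd = max_disp_px(params)
    nonlink = params.nonlink_cost_factor * maxd**2

    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    admissible = np.sqrt(d2) <= maxd
    link_cost = np.where(admissible, d2, np.inf)

    big = np.full((n + m, n + m), np.inf)
    big[:n, :m] = link_cost
    big[:n, m:][np.diag_indices(n)] = nonlink  # deaths
    big[n:, :m][np.diag_indices(m)] = nonlink  # births
    big[n:, m:] = np.where(admissible.T, 0.0, np.inf)  # completion block

    # deterministic lexicographic tie-break: tiny rank-ordered perturbation
    finite = np.isfinite(big[:n, :m])
    if finite.any():
        ranks = np.arange(n * m, dtype=float).reshape(n, m)
        eps = 1e-9 / (n * m)
        big[:n, :m] += np.where(finite, eps * ranks, 0.0)

    rows, cols = linear_sum_assignment(big)
    links = [
        (a[i].id, b[j].id)
        for i, j in zip(rows, cols)
        if i < n and j < m
    ]
    return sorted(links)


def link_movie(
    spots_by_frame: list[list[Spot]], params: LinkParams
) -> list[list[tuple[int, int]]]:
    """Links for every consecutive frame pair of a movie."""
    return [
        link_frame_pair(spots_by_frame[t], spots_by_frame[t + 1], params)
        for t in range(len(spots_by_frame) - 1)
    ]


def build_tracks(
    links_per_pair: list[list[tuple[int, int]]],
    spots_by_frame: list[list[Spot]],
) -> list[Track]:
    """Chain frame-pair links into gap-free tracks.

    Every spot ends up in exactly one track; spots with no links become
    length-1 tracks.  Track ids follow (first frame, first-spot id) order.
    """
    spot_lookup: dict[tuple[int, int], Spot] = {}
    for t, frame_spots in enumerate(spots_by_frame):
        for s in frame_spots:
            key = (t, s.id)
            if key in spot_lookup:
                raise ValueError(f"duplicate spot id {s.id} in frame {t}")
            spot_lookup[key] = s

    successor: dict[tuple[int, int], tuple[int, int]] = {}
    has_pred: set[tuple[int, int]] = set()
    for t, links in enumerate(links_per_pair):
        seen_a: set[int] = set()
        seen_b: set[int] = set()
        for id_a, id_b in links:
            if id_a in seen_a or id_b in seen_b:
                raise ValueError("conflicting links: a spot appears twice")
            seen_a.add(id_a)
            seen_b.add(id_b)
            if (t, id_a) not in spot_lookup or (t + 1, id_b) not in spot_lookup:
                raise ValueError("link references a non-existent spot")
            successor[(t, id_a)] = (t + 1, id_b)
            has_pred.add((t + 1, id_b))

    starts = sorted(k for k in spot_lookup if k not in has_pred)
    tracks: list[Track] = []
    for start in starts:
        chain = [start]
        while chain[-1] in successor:
            chain.append(successor[chain[-1]])
        tracks.append(Track(len(tracks), [spot_lookup[k] for k in chain]))
    return tracks


def lifetime_filter(tracks: list[Track], min_frames: int = 5) -> list[Track]:
    """Keep tracks lasting at least ``min_frames`` frames.

    The default of 5 retains tracks with a lifetime of over four frames
    ("over four" read as point count ≥ 5, the inclusive-boundary reading).
    """
    return [t for t in tracks if len(t) >= min_frames]
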