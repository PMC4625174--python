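"""Permutation test for a difference of means, and the efflux percentage.

The permutation test compares two group means without assuming normality:
group labels are re-assigned (preserving group sizes) and the observed
difference is ranked against the permutation distribution.  Random
(Monte-Carlo) permutations use the add-one correction
p = (#{|T_perm| >= |T_obs|} + 1) / (n_permutations + 1), which keeps the
p-value valid in (0, 1]; when the total number of distinct group
assignments is small (<= 20 000) the test switches to exhaustive
enumeration and the p-value is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = ["PermutationResult", "permutation_test_means", "efflux_percent"]

_EXHAUSTIVE_LIMIT = 20_000


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int | None
    two_sided: bool
    method: str = "montecarlo"  # or "exhaustive"

    def summary(self) -> str:
        side = "two-sided" if self.two_sided else "one-sided"
        return (
            f"permutation test for means ({side}, {self.method}, "
            f"{self.n_permutations} permutations): "
            f"observed diff = {self.observed_diff:.6g}, p = {self.p_value:.4g}"
        )


def permutation_test_means(
    x,
    y,
    n_permutations: int = 10_000,
    seed: int | None = None,
    two_sided: bool = True,
    exhaustive: str | bool = "auto",
) -> PermutationResult:
    """Permutation test for ``mean(x) - mean(y)``.

    Parameters
    ----------
    x, y : array-like
        The two samples (at least two observations each).
    n_permutations : int
        Monte-Carlo permutation count (ignored in exhaustive mode).
    seed : int, optional
        Seed for the Monte-Carlo label shuffles; the result is
        deterministic given identical inputs and seed.
    two_sided : bool
        Two-sided compares |T|; one-sided tests mean(x) > mean(y).
    exhaustive : "auto" | bool
        "auto" enumerates all C(n_x+n_y, n_x) assignments when that count
        is at most 20 000.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    observed = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    # tolerance for the >= rank comparison: float sums of permuted groups
    # can differ from the observed sum by rounding alone
    tol = 1e-12 * max(1.0, float(np.abs(pooled).max())) * n

    total = comb(n, nx)
    use_exhaustive = exhaustive is True or (exhaustive == "auto" and total <= _EXHAUSTIVE_LIMIT)

    def extremity(t_perm: np.ndarray) -> np.ndarray:
        if two_sided:
            return np.abs(t_perm) >= abs(observed) - tol
        return t_perm >= observed - tol

    if use_exhaustive:
        pooled_sum = pooled.sum()
        t_perm = np.empty(total)
        for k, idx in enumerate(combinations(range(n), nx)):
            sx = pooled[list(idx)].sum()
            t_perm[k] = sx / nx - (pooled_sum - sx) / (n - nx)
        p = float(extremity(t_perm).mean())
        return PermutationResult(observed, p, total, seed, two_sided, "exhaustive")

    rng = np.random.default_rng(seed)
    # vectorised shuffles: argsort of uniforms gives independent permutations
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm = pooled[order]
    t_perm = perm[:, :nx].mean(axis=1) - perm[:, nx:].mean(axis=1)
    hits = int(extremity(t_perm).sum())
    p = (hits + 1) / (n_permutations + 1)
    return PermutationResult(observed, float(p), n_permutations, seed, two_sided)


def efflux_percent(counts_media: float, counts_cells: float) -> float:
    """Cholesterol efflux percentage: media counts over total counts × 100."""
    if counts_media < 0 or counts_cells < 0:
        raise ValueError("counts must be non-negative")
    total = counts_media + counts_cells
    if total <= 0:
        raise ValueError("total counts must be positive")
    return 100.0 * counts_media / total
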