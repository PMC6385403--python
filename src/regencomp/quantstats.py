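"""Estimation statistics for cell-count comparisons.

Implements the statistics used downstream of microscopy quantification:
Mann-Whitney U tests (exact by enumeration for small tie-free samples,
otherwise a tie- and continuity-corrected normal approximation), bootstrap
difference-of-means with a 95% percentile confidence interval, and the
wound/middle/distal equal-thirds partition of cell coordinates along the
wound axis. Image segmentation itself is out of scope; inputs are
per-animal counts or cell coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

_EXACT_LIMIT = 12


@dataclass(frozen=True)
class CountComparison:
    group_x: tuple
    group_y: tuple
    delta_mean: float
    ci95: tuple[float, float]
    u_statistic: float
    p: float


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U_x = #{(i, j): x_i > y_j} with half credit for ties."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p) with U = min(U_x, U_y).

    ``mode``: "exact" enumerates all group labelings of the pooled data and
    doubles the lower tail of U (capped at 1); "approx" uses the normal
    approximation with tie and continuity corrections; "auto" picks exact for
    tie-free samples with n + m <= 12.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (n + m <= _EXACT_LIMIT and not has_ties) else "approx"

    ux = _u_statistic(x, y)
    uy = n * m - ux
    u = min(ux, uy)

    if mode == "exact":
        count = total = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            if _u_statistic(pooled[mask], pooled[~mask]) <= u:
                count += 1
            total += 1
        p = min(1.0, 2.0 * count / total)
    elif mode == "approx":
        N = n + m
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1))
        var = n * m / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            return u, 1.0
        z = (u - n * m / 2.0 + 0.5) / np.sqrt(var)  # continuity-corrected
        p = min(1.0, 2.0 * stats.norm.cdf(z))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return u, float(p)


def mean_difference_ci(
    x, y, n_boot: int = 5000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Difference of means mean(y) - mean(x) with a 95% percentile bootstrap CI.

    Groups are resampled independently with replacement; deterministic for a
    fixed seed.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    rng = np.random.default_rng(seed)
    delta = float(y.mean() - x.mean())
    bx = rng.choice(x, size=(n_boot, len(x)), replace=True).mean(axis=1)
    by = rng.choice(y, size=(n_boot, len(y)), replace=True).mean(axis=1)
    boots = by - bx
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return delta, (float(lo), float(hi))


def compare_counts(x, y, n_boot: int = 5000, seed: int = 0, mode: str = "auto") -> CountComparison:
    """Bundle the U test and bootstrap difference of means for two groups."""
    u, p = mann_whitney_u(x, y, mode=mode)
    delta, ci = mean_difference_ci(x, y, n_boot=n_boot, seed=seed)
    return CountComparison(tuple(x), tuple(y), delta, ci, u, p)


def tripartite_counts(
    cell_positions,
    axis_extent: float,
    areas=None,
    size_gate: tuple[float, float] | None = None,
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Counts and fractions of cells in the wound/middle/distal thirds.

    Positions are distances from the wound edge along the wound axis, within
    [0, axis_extent]; the extent is split into three equal-width bins and
    boundary points fall to the wound-ward (lower) bin. Optional per-cell
    areas with a (min, max) ``size_gate`` reproduce the particle-size filter
    applied upstream of counting.
    """
    pos = np.asarray(list(cell_positions), dtype=float)
    if axis_extent <= 0:
        raise ValueError("axis_extent must be positive")
    if len(pos) and (pos.min() < 0 or pos.max() > axis_extent):
        raise ValueError("positions must lie within [0, axis_extent]")
    if size_gate is not None:
        if areas is None:
            raise ValueError("size_gate requires per-cell areas")
        areas = np.asarray(list(areas), dtype=float)
        keep = (areas >= size_gate[0]) & (areas <= size_gate[1])
        pos = pos[keep]
    e1, e2 = axis_extent / 3.0, 2.0 * axis_extent / 3.0
    wound = int(np.sum(pos <= e1))
    middle = int(np.sum((pos > e1) & (pos <= e2)))
    distal = int(np.sum(pos > e2))
    total = max(wound + middle + distal, 1)
    fracs = (wound / total, middle / total, distal / total)
    return (wound, middle, distal), fracs
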