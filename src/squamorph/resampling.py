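"""Morphospace disparity metrics with resampling uncertainty, permutation
tests, NPMANOVA and snake-centroid augmentation.

Two disparity metrics are implemented: the sum of per-axis score variances
(over all morphospace axes) and the convex hull volume in PC1–PC3. Bootstrap
percentile intervals (default 500 iterations, 95%) quantify uncertainty;
rarefaction resamples without replacement to a common n so the
sample-size-sensitive hull metric can be compared fairly across bins.
Between-group differences use membership-permutation nulls; morphospace
positioning is compared with NPMANOVA (PERMANOVA-style pseudo-F on Euclidean
distances over all retained axes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .morphometry import AlignedShapes, Morphospace
from .size import PermTestResult

__all__ = [
    "DisparityEstimate",
    "NpmanovaResult",
    "SnakeCentroid",
    "DegenerateGeometryError",
    "sum_of_variances",
    "hull_volume",
    "bootstrap_ci",
    "rarefied_metric",
    "permutation_metric_test",
    "npmanova",
    "snake_centroid",
    "snake_augment",
]


class DegenerateGeometryError(ValueError):
    """Hull volume requested for < 4 points or a (near-)coplanar point set."""


@dataclass(frozen=True)
class DisparityEstimate:
    """A disparity metric value with its resampling confidence interval."""

    metric: str
    group: str
    n: int
    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_boot: int = 0
    seed: Optional[int] = None
    rarefied_to: Optional[int] = None


@dataclass(frozen=True)
class NpmanovaResult:
    """NPMANOVA pseudo-F with its label-permutation p-value."""

    pseudo_f: float
    p_value: float
    n_permutations: int
    group_sizes: dict
    seed: Optional[int] = None
    exhaustive: bool = False


@dataclass(frozen=True)
class SnakeCentroid:
    """Mean aligned shape of the designated snake taxa and its projection
    into the fitted morphospace."""

    shape: np.ndarray        # (k, 2) mean aligned configuration
    scores: np.ndarray       # (n_axes,) morphospace projection
    member_taxa: tuple = ()


def sum_of_variances(scores: np.ndarray) -> float:
    """Sum over axes of the sample variance (n−1 denominator) of the group's
    morphospace scores; requires n >= 2 rows."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] < 2:
        raise ValueError("sum of variances requires n >= 2")
    return float(scores.var(axis=0, ddof=1).sum())


def hull_volume(scores3: np.ndarray) -> float:
    """Volume of the 3-D convex hull of the group's PC1–PC3 scores.

    Raises :class:`DegenerateGeometryError` (never a silent 0) for fewer than
    4 points or a degenerate (coplanar/collinear) configuration.
    """
    pts = np.atleast_2d(np.asarray(scores3, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError(f"hull volume needs 3-D points, got {pts.shape[1]}-D")
    if pts.shape[0] < 4:
        raise DegenerateGeometryError(
            f"hull volume requires >= 4 points, got {pts.shape[0]}")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"degenerate point configuration (coplanar within tolerance): {exc}"
        ) from exc
    return float(hull.volume)


_METRICS: dict[str, Callable[[np.ndarray], float]] = {
    "sum_of_variances": sum_of_variances,
    "hull_volume": hull_volume,
}


def _resolve_metric(metric) -> tuple[str, Callable[[np.ndarray], float]]:
    if callable(metric):
        return getattr(metric, "__name__", "custom"), metric
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; options: {sorted(_METRICS)}")
    return metric, _METRICS[metric]


def bootstrap_ci(rows: np.ndarray, metric="sum_of_variances", n_boot: int = 500,
                 level: float = 0.95, seed: Optional[int] = None,
                 group: str = "") -> DisparityEstimate:
    """Percentile bootstrap CI for a disparity metric.

    Rows are resampled with replacement at the original n; the point estimate
    is the metric on the observed group. Iterates where the metric is
    undefined (e.g. a degenerate bootstrap hull) are dropped; if more than
    half fail the estimate is refused.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    name, fn = _resolve_metric(metric)
    value = fn(rows)
    rng = np.random.default_rng(seed)
    n = rows.shape[0]
    vals = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(fn(rows[idx]))
        except (DegenerateGeometryError, ValueError):
            failures += 1
    if n_boot and failures > 0.5 * n_boot:
        raise DegenerateGeometryError(
            f"{name}: metric failed in {failures}/{n_boot} bootstrap iterates")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)]) if vals else (None, None)
    return DisparityEstimate(metric=name, group=group, n=n, value=value,
                             ci_low=float(lo), ci_high=float(hi),
                             n_boot=n_boot, seed=seed)


def rarefied_metric(rows: np.ndarray, metric, target_n: int, n_iter: int = 500,
                    level: float = 0.95, seed: Optional[int] = None,
                    group: str = "", with_replacement: bool = False
                    ) -> DisparityEstimate:
    """Rarefied disparity: subsample ``target_n`` rows (without replacement
    by default) per iterate and report the mean metric with a percentile CI.

    Makes sample-size-sensitive metrics (the convex hull volume in
    particular) comparable across bins of unequal n.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n = rows.shape[0]
    if target_n > n:
        raise ValueError(f"target_n ({target_n}) exceeds group size ({n})")
    name, fn = _resolve_metric(metric)
    rng = np.random.default_rng(seed)
    vals = []
    failures = 0
    for _ in range(n_iter):
        if with_replacement:
            idx = rng.integers(0, n, size=target_n)
        else:
            idx = rng.choice(n, size=target_n, replace=False)
        try:
            vals.append(fn(rows[idx]))
        except (DegenerateGeometryError, ValueError):
            failures += 1
    if n_iter and failures > 0.5 * n_iter:
        raise DegenerateGeometryError(
            f"{name}: metric failed in {failures}/{n_iter} rarefaction iterates")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return DisparityEstimate(metric=name, group=group, n=n,
                             value=float(np.mean(vals)), ci_low=float(lo),
                             ci_high=float(hi), n_boot=n_iter, seed=seed,
                             rarefied_to=target_n)


def permutation_metric_test(group_a: np.ndarray, group_b: np.ndarray, metric,
                            n_iter: int = 1000, seed: Optional[int] = None,
                            tail: str = "two-sided", exhaustive: bool = False
                            ) -> PermTestResult:
    """Membership-permutation test for a multivariate disparity difference.

    Same pooling/reshuffling null as the univariate size test, applied to
    morphospace score rows and a disparity metric. ``exhaustive=True``
    enumerates every split of the pooled rows (exact; small n only).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if tail not in ("two-sided", "greater"):
        raise ValueError(f"unknown tail {tail!r}")
    name, fn = _resolve_metric(metric)
    observed = fn(b) - fn(a)
    pool = np.vstack([a, b])
    n_a, n_tot = a.shape[0], pool.shape[0]

    if exhaustive:
        null = []
        for comb in combinations(range(n_tot), n_a):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(comb)] = True
            null.append(fn(pool[~mask]) - fn(pool[mask]))
        null = np.asarray(null)
        if tail == "two-sided":
            hits = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
        else:
            hits = int(np.sum(null >= observed - 1e-12))
        return PermTestResult(name, float(observed), int(null.size),
                              hits / null.size, None, tail, True, null)

    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(n_tot)
        null[i] = fn(pool[perm[n_a:]]) - fn(pool[perm[:n_a]])
    if tail == "two-sided":
        hits = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    else:
        hits = int(np.sum(null >= observed - 1e-12))
    p = (1 + hits) / (1 + n_iter)
    return PermTestResult(name, float(observed), n_iter, p, seed, tail, False, null)


# ---------------------------------------------------------------------------
# NPMANOVA

def _pseudo_f_from_d2(d2: np.ndarray, labels: np.ndarray) -> float:
    """Anderson-style pseudo-F from a squared Euclidean distance matrix."""
    n = d2.shape[0]
    groups, counts = np.unique(labels, return_counts=True)
    a = groups.size
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g, ng in zip(groups, counts):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def npmanova(scores: np.ndarray, labels: Sequence, n_perm: int = 999,
             seed: Optional[int] = None, exhaustive: bool = False
             ) -> NpmanovaResult:
    """Non-parametric MANOVA (PERMANOVA) on Euclidean distances.

    Partitions among- vs within-group sums of squared distances over all
    supplied axes into a pseudo-F ratio; significance by permuting group
    labels, p = (1 + #{F_perm >= F_obs}) / (1 + n_perm). ``exhaustive=True``
    enumerates all distinct label assignments instead (two groups only).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    if labels.size != scores.shape[0]:
        raise ValueError("labels length must match number of score rows")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("NPMANOVA requires >= 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise ValueError(f"every group needs n >= 2; too small: {small}")
    diff = scores[:, None, :] - scores[None, :, :]
    d2 = (diff ** 2).sum(axis=-1)
    f_obs = _pseudo_f_from_d2(d2, labels)
    sizes = {str(g): int(c) for g, c in zip(groups, counts)}

    if exhaustive:
        if groups.size != 2:
            raise ValueError("exhaustive NPMANOVA supports exactly 2 groups")
        n = labels.size
        n_a = int(counts[0])
        fs = []
        for comb in combinations(range(n), n_a):
            lab = np.full(n, groups[1], dtype=labels.dtype)
            lab[list(comb)] = groups[0]
            fs.append(_pseudo_f_from_d2(d2, lab))
        fs = np.asarray(fs)
        hits = int(np.sum(fs >= f_obs - 1e-12))
        return NpmanovaResult(float(f_obs), hits / fs.size, int(fs.size),
                              sizes, None, True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(labels.size)]
        if _pseudo_f_from_d2(d2, perm_labels) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return NpmanovaResult(float(f_obs), p, n_perm, sizes, seed, False)


# ---------------------------------------------------------------------------
# Snake-centroid augmentation

def snake_centroid(aligned: AlignedShapes, space: Morphospace,
                   snake_ids: Sequence[str]) -> SnakeCentroid:
    """Mean aligned shape of the designated snake taxa, projected through the
    fitted morphospace."""
    ids = list(snake_ids)
    if not ids:
        raise ValueError("snake_ids must be non-empty")
    index = {t: i for i, t in enumerate(aligned.taxa)}
    missing = [t for t in ids if t not in index]
    if missing:
        raise ValueError(f"snake taxa not in aligned shapes: {missing}")
    shape = aligned.coords[[index[t] for t in ids]].mean(axis=0)
    scores = space.project(shape.reshape(1, -1))[0]
    return SnakeCentroid(shape=shape, scores=scores, member_taxa=tuple(ids))


def snake_augment(group_scores: dict[str, np.ndarray], centroid: SnakeCentroid,
                  target_bins: Sequence[str]) -> dict[str, np.ndarray]:
    """Add the snake centroid as one pseudo-member of each target bin.

    Returns a new group→scores mapping; bins not listed are passed through
    unchanged, and the original arrays are never modified.
    """
    out = {}
    for label, rows in group_scores.items():
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if label in target_bins:
            out[label] = np.vstack([rows, centroid.scores[: rows.shape[1]][None, :]])
        else:
            out[label] = rows.copy()
    missing = set(target_bins) - set(group_scores)
    if missing:
        raise ValueError(f"target bins not present: {sorted(missing)}")
    return out
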