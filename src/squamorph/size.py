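"""Jaw-size series and size-disparity tests.

Lower jaw (mandible) length is used as a body-size proxy; analyses run on
log10-transformed lengths by default. Within-bin disparity is quantified as
the univariate range (max − min) and sample standard deviation. Shifts
between bins are tested with membership-permutation tests (pool the two bins,
reshuffle membership at the original sizes, recompute the disparity
difference) and with Welch / Student two-sample t contrasts on means.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .stratigraphy import InputError

__all__ = [
    "JawSizeRecord",
    "BinDisparity",
    "PermTestResult",
    "read_jaw_csv",
    "log10_lengths",
    "bin_disparity",
    "value_range",
    "sample_sd",
    "permutation_disparity_test",
    "welch_t",
    "student_t",
]


@dataclass(frozen=True)
class JawSizeRecord:
    """Maximum known mandible length (mm) for a genus, with range/habitat labels."""

    genus: str
    jaw_length_mm: float
    habitat: str
    clade: str
    fad_stage: str
    lad_stage: str

    def __post_init__(self) -> None:
        if not self.jaw_length_mm > 0:
            raise InputError(
                f"genus {self.genus!r}: jaw length must be positive, "
                f"got {self.jaw_length_mm}"
            )


@dataclass(frozen=True)
class BinDisparity:
    """Range, sample SD and mean of (log10) jaw lengths within one bin."""

    label: str
    n: int
    range: float
    sd: Optional[float]
    mean: float


@dataclass(frozen=True)
class PermTestResult:
    """Observed between-bin disparity difference with its permutation null.

    ``p_value`` uses the finite-sample estimator (1 + b) / (1 + N) where b
    counts null draws at least as extreme as the observation under the chosen
    tail; with ``exhaustive=True`` the full set of membership splits is
    enumerated instead and p is the exact count-based proportion.
    """

    statistic: str
    observed_diff: float
    n_iterations: int
    p_value: float
    seed: Optional[int]
    tail: str = "two-sided"
    exhaustive: bool = False
    null_distribution: Optional[np.ndarray] = field(default=None, repr=False, compare=False)


def read_jaw_csv(path: str | Path) -> list[JawSizeRecord]:
    """Read jaw length records from CSV with header
    genus,jaw_length_mm,habitat,clade,fad_stage,lad_stage."""
    out: list[JawSizeRecord] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"genus", "jaw_length_mm", "habitat", "clade", "fad_stage", "lad_stage"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise InputError(f"{path}: missing required columns {sorted(missing)}")
        for rownum, row in enumerate(reader, start=2):
            try:
                out.append(
                    JawSizeRecord(
                        genus=row["genus"],
                        jaw_length_mm=float(row["jaw_length_mm"]),
                        habitat=row["habitat"],
                        clade=row["clade"],
                        fad_stage=row["fad_stage"],
                        lad_stage=row["lad_stage"],
                    )
                )
            except (InputError, ValueError) as exc:
                errors.append(f"row {rownum}: {exc}")
    if errors:
        raise InputError(f"{path}: {len(errors)} invalid rows:\n" + "\n".join(errors))
    return out


def log10_lengths(lengths_mm: Sequence[float]) -> np.ndarray:
    """Base-10 logarithm of jaw lengths; units log10(mm). Lengths must be > 0."""
    arr = np.asarray(lengths_mm, dtype=float)
    if (arr <= 0).any():
        bad = arr[arr <= 0]
        raise InputError(f"non-positive jaw lengths: {bad.tolist()}")
    return np.log10(arr)


def value_range(values: np.ndarray) -> float:
    """max − min; requires at least one value."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("range requires n >= 1")
    return float(values.max() - values.min())


def sample_sd(values: np.ndarray) -> float:
    """Sample standard deviation with the n−1 denominator; requires n >= 2."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("sample SD requires n >= 2")
    return float(np.std(values, ddof=1))


_STATS: dict[str, Callable[[np.ndarray], float]] = {
    "range": value_range,
    "sd": sample_sd,
}


def bin_disparity(values_by_bin: dict[str, Sequence[float]]) -> list[BinDisparity]:
    """Per-bin range, sample SD and mean. SD is reported absent (None) for
    singleton bins rather than raising."""
    out = []
    for label, vals in values_by_bin.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 1:
            raise ValueError(f"bin {label!r} is empty")
        sd = sample_sd(arr) if arr.size >= 2 else None
        out.append(
            BinDisparity(
                label=label,
                n=int(arr.size),
                range=value_range(arr),
                sd=sd,
                mean=float(arr.mean()),
            )
        )
    return out


def _null_diffs_exhaustive(pool: np.ndarray, n_a: int,
                           stat: Callable[[np.ndarray], float]) -> np.ndarray:
    idx = np.arange(pool.size)
    diffs = []
    for comb in combinations(idx, n_a):
        mask = np.zeros(pool.size, dtype=bool)
        mask[list(comb)] = True
        diffs.append(stat(pool[~mask]) - stat(pool[mask]))
    return np.asarray(diffs)


def permutation_disparity_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    statistic: str = "range",
    n_iter: int = 1000,
    seed: Optional[int] = None,
    tail: str = "two-sided",
    exhaustive: bool = False,
) -> PermTestResult:
    """Membership-permutation test for a disparity difference between two bins.

    The observed difference is stat(B) − stat(A). The null pools both bins,
    reshuffles membership at the original group sizes and recomputes the
    difference, ``n_iter`` times (default 1000). ``exhaustive=True``
    enumerates every membership split instead (exact test; feasible for small
    pooled n) and ignores ``n_iter``/``seed``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}; options: {sorted(_STATS)}")
    if tail not in ("two-sided", "greater"):
        raise ValueError(f"unknown tail {tail!r}")
    stat = _STATS[statistic]
    observed = stat(b) - stat(a)
    pool = np.concatenate([a, b])

    if exhaustive:
        null = _null_diffs_exhaustive(pool, a.size, stat)
        if tail == "two-sided":
            hits = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
        else:
            hits = int(np.sum(null >= observed - 1e-12))
        p = hits / null.size
        return PermTestResult(statistic, float(observed), int(null.size), p,
                              None, tail, True, null)

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(pool)
        null[i] = stat(perm[a.size:]) - stat(perm[: a.size])
    if tail == "two-sided":
        hits = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    else:
        hits = int(np.sum(null >= observed - 1e-12))
    p = (1 + hits) / (1 + n_iter)
    return PermTestResult(statistic, float(observed), n_iter, p, seed, tail, False, null)


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test (unequal variances): returns (t, df, p) with
    Welch–Satterthwaite degrees of freedom and a two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    _check_t_inputs(a, b)
    res = _sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def student_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Student pooled-variance two-sample t-test: (t, df = nA + nB − 2, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    _check_t_inputs(a, b)
    res = _sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _check_t_inputs(a: np.ndarray, b: np.ndarray) -> None:
    if a.size < 2 or b.size < 2:
        raise ValueError("t-tests require n >= 2 in both groups")
    if math.isclose(np.var(a) + np.var(b), 0.0):
        raise ValueError("zero variability in both groups: t undefined")
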