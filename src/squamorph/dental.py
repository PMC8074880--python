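"""Dental morphotype composition per time bin and Bray–Curtis turnover.

Each genus carries one or more discrete tooth-shape categories (morphotypes);
heterodont taxa carry several. The counting unit is the genus–morphotype pair
("occurrence"), so a heterodont genus contributes to every morphotype it
carries and the proportion denominator is total occurrences in the bin, not
genera. Between-bin turnover is quantified with pairwise Bray–Curtis
dissimilarity on either relative (proportional) or absolute compositions.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import distance as _ssd

from .stratigraphy import InputError

__all__ = [
    "DegenerateBinError",
    "read_assignments_csv",
    "build_count_table",
    "relative_proportions",
    "bray_curtis",
    "dissimilarity_matrix",
]


class DegenerateBinError(ValueError):
    """A bin with zero total occurrences entered a computation that needs
    positive row sums."""


def read_assignments_csv(path: str | Path,
                         vocabulary: Optional[Sequence[str]] = None
                         ) -> dict[str, set[str]]:
    """Read genus → morphotype-set assignments from a CSV with columns
    genus,morphotypes where morphotypes is a semicolon-separated code list."""
    out: dict[str, set[str]] = {}
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if not {"genus", "morphotypes"} <= set(reader.fieldnames or []):
            raise InputError(f"{path}: expected columns genus,morphotypes")
        for rownum, row in enumerate(reader, start=2):
            codes = {c.strip() for c in row["morphotypes"].split(";") if c.strip()}
            if not codes:
                errors.append(f"row {rownum}: genus {row['genus']!r} has no morphotypes")
                continue
            if vocabulary is not None:
                bad = codes - set(vocabulary)
                if bad:
                    errors.append(
                        f"row {rownum}: genus {row['genus']!r} has unknown codes {sorted(bad)}"
                    )
                    continue
            out[row["genus"]] = codes
    if errors:
        raise InputError(f"{path}: {len(errors)} invalid rows:\n" + "\n".join(errors))
    return out


def build_count_table(
    assignments: Mapping[str, set[str]],
    bin_genera: Mapping[str, set[str]],
    morphotypes: Sequence[str],
    habitat_filter: Optional[str] = None,
    habitats: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Count genus–morphotype occurrences per bin.

    Parameters
    ----------
    assignments
        genus → set of morphotype codes (heterodont taxa carry several).
    bin_genera
        bin label → set of member genera (from stratigraphy.assign_to_bins).
    morphotypes
        ordered morphotype vocabulary fixing the column order.
    habitat_filter
        if given (e.g. ``"terrestrial"``), keep only genera with that habitat;
        requires ``habitats`` (genus → habitat).

    Returns
    -------
    DataFrame of non-negative integer counts, bins × morphotypes.
    """
    if habitat_filter is not None and habitats is None:
        raise ValueError("habitat_filter requires a genus→habitat mapping")
    missing = sorted(
        {g for genera in bin_genera.values() for g in genera} - set(assignments)
    )
    if missing:
        raise InputError(
            f"{len(missing)} genera lack morphotype assignments: {missing[:10]}"
        )
    tbl = pd.DataFrame(
        0, index=list(bin_genera.keys()), columns=list(morphotypes), dtype=int
    )
    for label, genera in bin_genera.items():
        for genus in genera:
            if habitat_filter is not None and habitats.get(genus) != habitat_filter:
                continue
            for code in assignments[genus]:
                if code not in tbl.columns:
                    raise InputError(
                        f"genus {genus!r} carries code {code!r} outside the vocabulary"
                    )
                tbl.loc[label, code] += 1
    return tbl


def relative_proportions(tbl: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise a count table so each bin's composition sums to 1."""
    sums = tbl.sum(axis=1)
    zero = sums[sums == 0].index.tolist()
    if zero:
        raise DegenerateBinError(f"bins with zero occurrences: {zero}")
    return tbl.div(sums, axis=0)


def bray_curtis(u, v) -> float:
    """Bray–Curtis dissimilarity Σ|u−v| / Σ(u+v) between two non-negative
    composition vectors; 0 = identical, 1 = disjoint supports."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("composition vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("composition vectors must be non-negative")
    if u.sum() + v.sum() == 0:
        raise DegenerateBinError("Bray-Curtis undefined for two all-zero vectors")
    return float(_ssd.braycurtis(u, v))


def dissimilarity_matrix(tbl: pd.DataFrame, mode: str = "relative") -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity between bins.

    ``mode="relative"`` (default) compares proportional compositions, making
    the matrix invariant to per-bin sampling intensity; ``mode="absolute"``
    compares raw occurrence counts.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    if len(tbl) < 2:
        raise ValueError("need at least 2 bins for a dissimilarity matrix")
    rows = relative_proportions(tbl) if mode == "relative" else tbl
    sums = tbl.sum(axis=1)
    zero = sums[sums == 0].index.tolist()
    if zero:
        raise DegenerateBinError(f"bins with zero occurrences: {zero}")
    dm = _ssd.squareform(_ssd.pdist(rows.to_numpy(dtype=float), metric="braycurtis"))
    np.fill_diagonal(dm, 0.0)
    return pd.DataFrame(dm, index=tbl.index, columns=tbl.index)
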