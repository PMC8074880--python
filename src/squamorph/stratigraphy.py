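"""Geological time scaffolding.

Stage tables with numeric age bounds, range-through presence of taxa across
stages, binning schemes (stage-level, multi-stage, epoch-level), and
stratigraphic midpoint ages. All temporal binning elsewhere in the package is
expressed against the :class:`StageTable` defined here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "Stage",
    "StageTable",
    "OccurrenceRecord",
    "BinScheme",
    "InputError",
    "ConfigurationError",
    "default_config",
    "default_stage_table",
    "epoch_bin_scheme",
    "size_test_bin_scheme",
    "stage_bin_scheme",
    "range_through_presence",
    "assign_to_bins",
    "midpoint_age",
    "read_occurrences_csv",
]


class InputError(ValueError):
    """Raised for invalid user-supplied data (unknown stages, bad values)."""


class ConfigurationError(ValueError):
    """Raised for inconsistent configuration (bad bin schemes, vocabularies)."""


def default_config() -> dict:
    """Load the packaged default configuration (stage ages, bin schemes,
    controlled vocabularies)."""
    text = resources.files("squamorph.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class Stage:
    """A geological stage with numeric age bounds in Ma (base older than top)."""

    name: str
    base_age: float
    top_age: float

    def __post_init__(self) -> None:
        if not self.base_age > self.top_age:
            raise ConfigurationError(
                f"stage {self.name!r}: base_age ({self.base_age}) must exceed "
                f"top_age ({self.top_age})"
            )


class StageTable:
    """Ordered sequence of geological stages, oldest first.

    Invariants enforced on construction: unique names, strictly decreasing
    ages, and shared boundaries between adjacent stages.
    """

    def __init__(self, stages: Sequence[Stage]):
        names = [s.name for s in stages]
        if len(set(names)) != len(names):
            raise ConfigurationError("stage names must be unique")
        for older, younger in zip(stages, stages[1:]):
            if abs(older.top_age - younger.base_age) > 1e-9:
                raise ConfigurationError(
                    f"stages {older.name!r} and {younger.name!r} do not share a "
                    f"boundary ({older.top_age} vs {younger.base_age})"
                )
        self.stages: tuple[Stage, ...] = tuple(stages)
        self._index: dict[str, int] = {s.name: i for i, s in enumerate(stages)}

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self):
        return iter(self.stages)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.stages]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise InputError(f"unknown stage name: {name!r}") from None

    def stage(self, name: str) -> Stage:
        return self.stages[self.index(name)]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "StageTable":
        return cls([Stage(r["name"], float(r["base_age"]), float(r["top_age"]))
                    for r in records])

    @classmethod
    def from_csv(cls, path: str | Path) -> "StageTable":
        """Read a stage table from CSV with columns stage,base_age,top_age."""
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            rows = [
                {"name": r["stage"], "base_age": r["base_age"], "top_age": r["top_age"]}
                for r in reader
            ]
        if not rows:
            raise InputError(f"empty stage table: {path}")
        return cls.from_records(rows)


def default_stage_table() -> StageTable:
    """The 14 stages Kimmeridgian through Maastrichtian with ICS 2020 ages."""
    return StageTable.from_records(default_config()["stages"])


@dataclass(frozen=True)
class OccurrenceRecord:
    """A genus' stratigraphic range plus habitat/clade (and optional diet)."""

    genus: str
    fad_stage: str
    lad_stage: str
    habitat: str
    clade: str
    diet: Optional[str] = None

    def validate(self, table: StageTable, vocab: Optional[Mapping] = None) -> None:
        i, j = table.index(self.fad_stage), table.index(self.lad_stage)
        if i > j:
            raise InputError(
                f"genus {self.genus!r}: first appearance ({self.fad_stage}) is "
                f"younger than last appearance ({self.lad_stage})"
            )
        if vocab is not None:
            if self.habitat not in vocab["habitats"]:
                raise InputError(f"genus {self.genus!r}: unknown habitat {self.habitat!r}")
            if self.clade not in vocab["clades"]:
                raise InputError(f"genus {self.genus!r}: unknown clade {self.clade!r}")
            if self.diet is not None and self.diet not in vocab["diets"]:
                raise InputError(f"genus {self.genus!r}: unknown diet {self.diet!r}")


@dataclass
class BinScheme:
    """Ordered, non-overlapping grouping of stages into labelled bins.

    Each bin's member stages must be contiguous in StageTable order.
    """

    bins: list[tuple[str, list[str]]]
    table: StageTable = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.table is None:
            self.table = default_stage_table()
        seen: set[str] = set()
        labels = [label for label, _ in self.bins]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("bin labels must be unique")
        for label, members in self.bins:
            if not members:
                raise ConfigurationError(f"bin {label!r} has no member stages")
            idx = sorted(self.table.index(m) for m in members)
            if idx != list(range(idx[0], idx[-1] + 1)):
                raise ConfigurationError(f"bin {label!r}: member stages not contiguous")
            overlap = seen & set(members)
            if overlap:
                raise ConfigurationError(
                    f"bin {label!r} overlaps earlier bins on stages {sorted(overlap)}"
                )
            seen |= set(members)
        self._stage_to_bin = {m: label for label, members in self.bins for m in members}

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.bins]

    def bin_of(self, stage: str) -> str:
        try:
            return self._stage_to_bin[stage]
        except KeyError:
            raise ConfigurationError(
                f"stage {stage!r} is not covered by this bin scheme"
            ) from None


def stage_bin_scheme(table: Optional[StageTable] = None) -> BinScheme:
    """One bin per stage — the finest scheme (dental composition analysis)."""
    table = table or default_stage_table()
    return BinScheme([(s.name, [s.name]) for s in table], table)


def epoch_bin_scheme(table: Optional[StageTable] = None) -> BinScheme:
    """Late Jurassic / Early Cretaceous / Late Cretaceous epoch bins."""
    table = table or default_stage_table()
    cfg = default_config()
    return BinScheme(
        [(b["label"], list(b["member_stages"])) for b in cfg["epoch_bins"]], table
    )


def size_test_bin_scheme(table: Optional[StageTable] = None) -> BinScheme:
    """Multi-stage bins used for the jaw-size contrasts
    (Aptian-Albian, Cenomanian-Turonian, Campanian)."""
    table = table or default_stage_table()
    cfg = default_config()
    return BinScheme(
        [(b["label"], list(b["member_stages"])) for b in cfg["size_test_bins"]], table
    )


def range_through_presence(rec: OccurrenceRecord, table: StageTable) -> list[str]:
    """All stages from first to last appearance inclusive, oldest first.

    Range-through sampling: a taxon is treated as present in every stage
    between its first and last appearance even if unsampled in between.
    """
    i, j = table.index(rec.fad_stage), table.index(rec.lad_stage)
    if i > j:
        raise InputError(
            f"genus {rec.genus!r}: fad_stage {rec.fad_stage!r} is younger than "
            f"lad_stage {rec.lad_stage!r}"
        )
    return table.names[i : j + 1]


def assign_to_bins(
    presences: Mapping[str, Sequence[str]],
    scheme: BinScheme,
    partial: bool = False,
) -> dict[str, set[str]]:
    """Map per-genus stage presence lists onto per-bin genus sets.

    A genus belongs to a bin iff any of its present stages falls in that bin;
    a genus spanning several bins belongs to each of them. A presence stage
    not covered by the scheme is a configuration error unless ``partial`` is
    set (for deliberately non-covering schemes such as the multi-stage
    size-test bins), in which case it is skipped.
    """
    out: dict[str, set[str]] = {label: set() for label in scheme.labels}
    for genus, stages in presences.items():
        for stage in stages:
            try:
                out[scheme.bin_of(stage)].add(genus)
            except ConfigurationError:
                if not partial:
                    raise
    return out


def midpoint_age(rec: OccurrenceRecord, table: StageTable) -> float:
    """Stratigraphic midpoint in Ma: halfway between the base of the first
    appearance stage and the top of the last appearance stage."""
    fad = table.stage(rec.fad_stage)
    lad = table.stage(rec.lad_stage)
    return (fad.base_age + lad.top_age) / 2.0


def read_occurrences_csv(
    path: str | Path,
    table: Optional[StageTable] = None,
    vocab: Optional[Mapping] = None,
) -> list[OccurrenceRecord]:
    """Read occurrence records from a CSV with header
    genus,fad_stage,lad_stage,habitat,clade[,diet]. Validation errors are
    aggregated and reported with row numbers."""
    table = table or default_stage_table()
    if vocab is None:
        vocab = default_config()
    records: list[OccurrenceRecord] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"genus", "fad_stage", "lad_stage", "habitat", "clade"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise InputError(f"{path}: missing required columns {sorted(missing)}")
        for rownum, row in enumerate(reader, start=2):
            rec = OccurrenceRecord(
                genus=row["genus"],
                fad_stage=row["fad_stage"],
                lad_stage=row["lad_stage"],
                habitat=row["habitat"],
                clade=row["clade"],
                diet=(row.get("diet") or None),
            )
            try:
                rec.validate(table, vocab)
            except (InputError, ConfigurationError) as exc:
                errors.append(f"row {rownum}: {exc}")
                continue
            records.append(rec)
    if errors:
        raise InputError(f"{path}: {len(errors)} invalid rows:\n" + "\n".join(errors))
    return records
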