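"""Muscle class schema for lower-limb segmentation.

The segmentation networks label 37 individual muscles of the lower limb
(plus background, class 0).  Class ids 1-37 are assigned alphabetically by
muscle name.  A subset of 23 muscles carries an ``included`` flag: only
those are used when summarising segmentation accuracy, because the others
cannot be segmented manually with acceptable repeatability and would bias
any comparison against a manual reference.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Sequence

N_MUSCLE_CLASSES = 37
BACKGROUND_CLASS = 0

_SECTIONS = ("hips", "thigh", "calf")


@dataclass(frozen=True)
class MuscleEntry:
    """One muscle class: id, name, report abbreviation, body section, inclusion flag."""

    class_id: int
    name: str
    abbreviation: str | None
    section: str
    included: bool


@dataclass(frozen=True)
class MuscleSchema:
    """The full ordered muscle class table."""

    entries: tuple[MuscleEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.class_id for e in self.entries]
        if ids != list(range(1, len(self.entries) + 1)):
            raise ValueError("class ids must be 1..N with no gaps")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("muscle names must be unique")
        bad = [e.section for e in self.entries if e.section not in _SECTIONS]
        if bad:
            raise ValueError(f"unknown body sections: {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[MuscleEntry]:
        return iter(self.entries)

    def __getitem__(self, class_id: int) -> MuscleEntry:
        if not 1 <= class_id <= len(self.entries):
            raise KeyError(f"class id {class_id} outside 1..{len(self.entries)}")
        return self.entries[class_id - 1]

    def by_name(self, name: str) -> MuscleEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def included_ids(self) -> tuple[int, ...]:
        return tuple(e.class_id for e in self.entries if e.included)

    @property
    def class_ids(self) -> tuple[int, ...]:
        return tuple(e.class_id for e in self.entries)


def _parse_rows(rows: Sequence[dict]) -> MuscleSchema:
    entries = []
    for row in rows:
        try:
            entries.append(
                MuscleEntry(
                    class_id=int(row["class_id"]),
                    name=row["name"],
                    abbreviation=row["abbreviation"] or None,
                    section=row["section"],
                    included=bool(int(row["included"])),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"corrupt schema row {row!r}") from exc
    entries.sort(key=lambda e: e.class_id)
    return MuscleSchema(entries=tuple(entries))


def load_schema() -> MuscleSchema:
    """Load the packaged 37-muscle schema (23 flagged for analysis inclusion)."""
    ref = resources.files("limbseg.data").joinpath("muscle_schema.csv")
    with ref.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    schema = _parse_rows(rows)
    if len(schema) != N_MUSCLE_CLASSES:
        raise ValueError(f"packaged schema has {len(schema)} classes, expected 37")
    return schema


def read_schema_csv(path: str) -> MuscleSchema:
    """Read a schema table from a CSV file (columns as the packaged resource)."""
    with open(path, newline="", encoding="utf-8") as fh:
        return _parse_rows(list(csv.DictReader(fh)))


def synthetic_schema(n_classes: int) -> MuscleSchema:
    """A synthetic schema of ``n_classes`` generic classes, all included.

    Used with phantom data, where volumes carry fewer classes than the full
    anatomical table.
    """
    if not 1 <= n_classes <= N_MUSCLE_CLASSES:
        raise ValueError("n_classes must be in 1..37")
    sections = _SECTIONS
    entries = tuple(
        MuscleEntry(
            class_id=k,
            name=f"phantom muscle {k:02d}",
            abbreviation=f"P{k}",
            section=sections[min(2, 3 * (k - 1) // n_classes)],
            included=True,
        )
        for k in range(1, n_classes + 1)
    )
    return MuscleSchema(entries=entries)
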