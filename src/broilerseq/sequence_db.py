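"""Sequence-database construction and text I/O.

Converts time-stamped behavior bouts into the per-broiler sequence-database
model: each broiler contributes one chronologically ordered sequence of
*window elements* (the behaviors seen in one 5-min analysis window). A bout
registers as a behavioral event only if it lasts at least ``min_bout_s``
(default 10 s, the transition rule of the annotation protocol); consecutive
surviving bouts of the same behavior merge into one code occurrence.

Text formats
------------
* Bout CSV: header ``broiler_id,condition,day,window_index,onset_s,duration_s,behavior``
  (UTF-8, ``#`` comment lines allowed).
* Sequence-database text: one line per transaction —
  tab-separated SID, 1-based transaction index, comma-joined codes.
  Empty windows are written with an empty code field so that round-trips
  preserve the window grid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from math import isfinite
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

from .errors import (
    DuplicateSidError,
    OverlapError,
    SchemaError,
    UnknownCodeError,
    WindowRangeError,
)
from .ethogram import Ethogram, load_default_ethogram
from .patterns import Pattern

__all__ = [
    "MIN_BOUT_S_DEFAULT",
    "WINDOW_S_DEFAULT",
    "N_WINDOWS_DEFAULT",
    "Bout",
    "BroilerSequence",
    "SequenceDatabase",
    "bouts_to_windows",
    "build_database",
    "sequence_size",
    "worked_example_database",
    "read_bout_csv",
    "write_bout_csv",
    "read_db_text",
    "write_db_text",
]

MIN_BOUT_S_DEFAULT = 10.0  # sustained-activity rule: shorter bouts are not events
WINDOW_S_DEFAULT = 300.0  # 5-min analysis clips
N_WINDOWS_DEFAULT = 14  # clips per broiler-day


@dataclass(frozen=True)
class Bout:
    """One continuous run of a single behavior within one analysis window.

    ``onset_s`` is measured from the start of the window.
    """

    broiler_id: str
    condition_id: str
    window_index: int
    onset_s: float
    duration_s: float
    behavior: str
    day: int | None = None

    def __post_init__(self) -> None:
        if self.window_index < 0:
            raise WindowRangeError(f"window_index must be >= 0, got {self.window_index}")
        if not (isfinite(self.onset_s) and self.onset_s >= 0):
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if not (isfinite(self.duration_s) and self.duration_s > 0):
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class BroilerSequence:
    """One broiler's chronologically ordered window elements, keyed by SID."""

    sid: str
    elements: tuple[tuple[str, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(tuple(el) for el in self.elements))

    @property
    def item_count(self) -> int:
        return sum(len(el) for el in self.elements)


@dataclass(frozen=True)
class SequenceDatabase:
    """An ordered collection of per-broiler sequences with unique SIDs."""

    sequences: tuple[BroilerSequence, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        seen: set[str] = set()
        for seq in self.sequences:
            if seq.sid in seen:
                raise DuplicateSidError(f"duplicate Sequence-Id {seq.sid!r}")
            seen.add(seq.sid)

    @property
    def n(self) -> int:
        """Number of sequences — the denominator of the support fraction."""
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[BroilerSequence]:
        return iter(self.sequences)

    def __getitem__(self, sid: str) -> BroilerSequence:
        for seq in self.sequences:
            if seq.sid == sid:
                return seq
        raise KeyError(sid)

    def alphabet(self) -> frozenset[str]:
        return frozenset(c for s in self.sequences for el in s.elements for c in el)


def build_database(sequences: Iterable[BroilerSequence]) -> SequenceDatabase:
    """Assemble sequences into a database, preserving input order."""
    return SequenceDatabase(tuple(sequences))


def worked_example_database() -> SequenceDatabase:
    """The two-broiler worked example: ``broiler_1 = <{E} {W} {D}>`` (size 3)
    and ``broiler_2 = <{Ld} {P}>`` (size 2), each transaction one item."""
    return build_database(
        [
            BroilerSequence("broiler_1", (("E",), ("W",), ("D",))),
            BroilerSequence("broiler_2", (("Ld",), ("P",))),
        ]
    )


def sequence_size(obj: Union[BroilerSequence, Pattern]) -> int:
    """Number of elements (steps) of a sequence or pattern.

    For a broiler sequence, empty windows do not count as steps (they hold
    no observation); for a pattern, elements are never empty so this is
    simply the element count.
    """
    if isinstance(obj, Pattern):
        return obj.size
    if isinstance(obj, BroilerSequence):
        return sum(1 for el in obj.elements if el)
    raise TypeError(f"expected BroilerSequence or Pattern, got {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def bouts_to_windows(
    bouts: Iterable[Bout],
    *,
    min_bout_s: float = MIN_BOUT_S_DEFAULT,
    window_s: float = WINDOW_S_DEFAULT,
    n_windows: int = N_WINDOWS_DEFAULT,
    ethogram: Ethogram | None = None,
    allow_mixed: bool = False,
) -> list[BroilerSequence]:
    """Convert bouts into one ``BroilerSequence`` per broiler.

    Per broiler and window: bouts are truncated at the window boundary,
    checked for overlap, discarded when their (within-window) duration is
    below ``min_bout_s``, ordered by onset, and adjacent same-behavior
    survivors are merged into a single code occurrence. Every sequence has
    exactly ``n_windows`` elements; windows without a qualifying bout stay
    empty, keeping transaction times aligned across broilers.

    Condition/day pooling is refused unless ``allow_mixed`` is set: each
    assessment day is a separate database.
    """
    eth = ethogram if ethogram is not None else load_default_ethogram()
    bouts = list(bouts)
    groups = {(b.condition_id, b.day) for b in bouts}
    if len(groups) > 1 and not allow_mixed:
        raise SchemaError(
            f"bouts span multiple condition/day groups {sorted(groups, key=repr)}; "
            "mine each assessment day separately or pass allow_mixed=True"
        )

    per_broiler: dict[str, dict[int, list[Bout]]] = {}
    for b in bouts:
        if b.behavior not in eth:
            raise UnknownCodeError(f"unknown behavior code {b.behavior!r} (broiler {b.broiler_id})")
        if b.window_index >= n_windows:
            raise WindowRangeError(
                f"window_index {b.window_index} >= n_windows {n_windows} (broiler {b.broiler_id})"
            )
        if b.onset_s >= window_s:
            raise WindowRangeError(
                f"onset {b.onset_s} s outside the {window_s} s window (broiler {b.broiler_id})"
            )
        per_broiler.setdefault(b.broiler_id, {}).setdefault(b.window_index, []).append(b)

    out: list[BroilerSequence] = []
    for broiler_id, windows in per_broiler.items():
        elements: list[tuple[str, ...]] = []
        for w in range(n_windows):
            within = sorted(windows.get(w, ()), key=lambda b: b.onset_s)
            # overlap check on the raw (truncated) bouts
            prev_end = -1.0
            for b in within:
                if b.onset_s < prev_end - 1e-9:
                    raise OverlapError(
                        f"overlapping bouts for broiler {broiler_id!r} in window {w}"
                        f" at {b.onset_s} s"
                    )
                prev_end = min(b.end_s, window_s)
            codes: list[str] = []
            for b in within:
                effective = min(b.duration_s, window_s - b.onset_s)
                if effective < min_bout_s - 1e-9:
                    continue  # sub-threshold bouts never register as events
                if codes and codes[-1] == b.behavior:
                    continue  # merge consecutive same-behavior survivors
                codes.append(b.behavior)
            elements.append(tuple(codes))
        out.append(BroilerSequence(broiler_id, tuple(elements)))
    return out


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------

BOUT_CSV_COLUMNS = (
    "broiler_id",
    "condition",
    "day",
    "window_index",
    "onset_s",
    "duration_s",
    "behavior",
)


def read_bout_csv(path: str | Path, ethogram: Ethogram | None = None) -> list[Bout]:
    """Read a bout annotation table.

    Validation is structural only: behaviors must exist in the ethogram and
    numeric fields must parse; the 10-s rule lives in windowing, so short
    bouts are accepted here. Offending rows are reported by number in a
    single :class:`~broilerseq.errors.SchemaError`.
    """
    eth = ethogram if ethogram is not None else load_default_ethogram()
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(line for line in fh if not line.startswith("#"))
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        missing = [c for c in BOUT_CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        bouts: list[Bout] = []
        bad_rows: list[int] = []
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            try:
                day_field = (row.get("day") or "").strip()
                bout = Bout(
                    broiler_id=row["broiler_id"].strip(),
                    condition_id=row["condition"].strip(),
                    window_index=int(row["window_index"]),
                    onset_s=float(row["onset_s"]),
                    duration_s=float(row["duration_s"]),
                    behavior=row["behavior"].strip(),
                    day=int(day_field) if day_field else None,
                )
                if bout.behavior not in eth:
                    raise UnknownCodeError(bout.behavior)
                bouts.append(bout)
            except (KeyError, TypeError, ValueError, UnknownCodeError, WindowRangeError):
                bad_rows.append(i)
    if bad_rows:
        raise SchemaError(f"{path}: invalid bout rows", rows=bad_rows)
    return bouts


def write_bout_csv(bouts: Iterable[Bout], path: str | Path, seed: int | None = None) -> None:
    """Write bouts as CSV; a ``# seed = N`` header records provenance."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed = {seed}\n")
        writer = csv.writer(fh)
        writer.writerow(BOUT_CSV_COLUMNS)
        for b in bouts:
            writer.writerow(
                [
                    b.broiler_id,
                    b.condition_id,
                    "" if b.day is None else b.day,
                    b.window_index,
                    f"{b.onset_s:g}",
                    f"{b.duration_s:g}",
                    b.behavior,
                ]
            )


def write_db_text(db: SequenceDatabase, path: str | Path, seed: int | None = None) -> None:
    """Write a database as transaction lines: SID, 1-based index, codes."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed = {seed}\n")
        for seq in db:
            for i, el in enumerate(seq.elements, start=1):
                fh.write(f"{seq.sid}\t{i}\t{','.join(el)}\n")


def read_db_text(path: str | Path, ethogram: Ethogram | None = None) -> SequenceDatabase:
    """Read a sequence-database text file written by :func:`write_db_text`."""
    eth = ethogram if ethogram is not None else load_default_ethogram()
    path = Path(path)
    per_sid: dict[str, dict[int, tuple[str, ...]]] = {}
    bad_rows: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                bad_rows.append(lineno)
                continue
            sid, idx_s, codes_s = parts
            try:
                idx = int(idx_s)
                if idx < 1:
                    raise ValueError(idx)
                codes = tuple(c.strip() for c in codes_s.split(",") if c.strip())
                for c in codes:
                    if c not in eth:
                        raise UnknownCodeError(c)
            except (ValueError, UnknownCodeError):
                bad_rows.append(lineno)
                continue
            per_sid.setdefault(sid, {})[idx - 1] = codes
    if bad_rows:
        raise SchemaError(f"{path}: invalid transaction lines", rows=bad_rows)
    sequences = []
    for sid, windows in per_sid.items():
        width = max(windows) + 1
        sequences.append(
            BroilerSequence(sid, tuple(windows.get(i, ()) for i in range(width)))
        )
    return build_database(sequences)
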