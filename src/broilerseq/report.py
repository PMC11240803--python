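"""Threshold-sweep reporting in the style of published pattern tables.

A sweep mines once at the lowest support level and then reports, at each
level of a strictly decreasing grid (default 1.0 down to 0.2 in steps of
0.1), the *new* maximal patterns: frequent patterns at that level with no
frequent proper superpattern at the same level, minus anything that is a
subpattern of — or identical to — a pattern already reported at a higher
level. This reproduces the presentation convention in which results of the
previous supports are excluded from lower rows because they are identical
subsets at the higher level.

The package ships machine-readable transcriptions of the four published
condition tables (10-broiler proof-of-concept study, two environments ×
two thermal conditions) so tally operations are testable without the raw
annotation data, which was never deposited. Two transcription entries carry
no printed carrier count; the loader records the count as missing rather
than inventing one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from .errors import InvalidLevelsError
from .ethogram import Ethogram, load_default_ethogram
from .gsp import mine, pattern_contains
from .patterns import Pattern, canonical_key, parse_pattern_notation
from .sequence_db import SequenceDatabase

__all__ = [
    "DEFAULT_LEVELS",
    "REFERENCE_CONDITIONS",
    "SweepRow",
    "SweepReport",
    "sweep",
    "collapse_rows",
    "tally_sizes",
    "total_patterns",
    "behavior_coverage",
    "max_reported_size",
    "format_report",
    "report_to_json",
    "load_reference_table",
]

DEFAULT_LEVELS: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)

REFERENCE_CONDITIONS: tuple[str, ...] = (
    "thermoneutral_plain",
    "thermoneutral_enriched",
    "heat_plain",
    "heat_enriched",
)

ReportedPattern = tuple[Pattern, Union[int, None]]


@dataclass(frozen=True)
class SweepRow:
    """Patterns newly reported at one (or several collapsed) support levels."""

    minsups: tuple[float, ...]
    patterns: tuple[ReportedPattern, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "minsups", tuple(self.minsups))
        object.__setattr__(self, "patterns", tuple(self.patterns))


@dataclass(frozen=True)
class SweepReport:
    """Ordered sweep rows for one condition; minsups strictly decrease."""

    condition_id: str
    rows: tuple[SweepRow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        flat = [m for row in self.rows for m in row.minsups]
        if any(b >= a for a, b in zip(flat, flat[1:])):
            raise InvalidLevelsError(f"sweep levels must strictly decrease, got {flat}")

    def all_patterns(self) -> list[ReportedPattern]:
        return [rp for row in self.rows for rp in row.patterns]


def _validate_levels(levels: Iterable[float]) -> tuple[float, ...]:
    levels = tuple(levels)
    if not levels:
        raise InvalidLevelsError("at least one support level is required")
    if any(not (0.0 < lv <= 1.0) for lv in levels):
        raise InvalidLevelsError(f"levels must lie in (0, 1], got {levels}")
    if any(b >= a for a, b in zip(levels, levels[1:])):
        raise InvalidLevelsError(f"levels must strictly decrease, got {levels}")
    return levels


def sweep(
    db: SequenceDatabase,
    levels: Iterable[float] = DEFAULT_LEVELS,
    *,
    condition_id: str = "",
    ethogram: Ethogram | None = None,
) -> SweepReport:
    """Run the MinSupport sweep and report new maximal patterns per level."""
    levels = _validate_levels(levels)
    eth = ethogram if ethogram is not None else load_default_ethogram()
    mined = mine(db, min(levels), ethogram=eth)
    rows: list[SweepRow] = []
    reported: list[Pattern] = []
    for level in levels:
        threshold = level * db.n - 1e-9
        frequent = [fp for fp in mined if fp.support_count >= threshold]
        maximal = [
            fp
            for fp in frequent
            if not any(
                other.pattern != fp.pattern and pattern_contains(other.pattern, fp.pattern)
                for other in frequent
            )
        ]
        new = [
            fp
            for fp in maximal
            if not any(pattern_contains(prev, fp.pattern) for prev in reported)
        ]
        new.sort(key=lambda fp: canonical_key(fp.pattern, eth))
        rows.append(SweepRow((level,), tuple((fp.pattern, fp.support_count) for fp in new)))
        reported.extend(fp.pattern for fp in new)
    return SweepReport(condition_id, tuple(rows))


def collapse_rows(report: SweepReport) -> SweepReport:
    """Group each reported set with the following empty levels (display form).

    Leading empty levels collapse into a single "None" row, matching the
    published table layout where e.g. levels 1.0 to 0.5 share one row.
    """
    grouped: list[tuple[list[float], tuple[ReportedPattern, ...]]] = []
    for row in report.rows:
        for minsup in row.minsups:
            if row.patterns and (not grouped or minsup == row.minsups[0]):
                grouped.append(([minsup], row.patterns))
            elif row.patterns:
                grouped[-1][0].append(minsup)
            elif grouped:
                grouped[-1][0].append(minsup)
            else:
                grouped.append(([minsup], ()))
    merged: list[SweepRow] = []
    for minsups, patterns in grouped:
        merged.append(SweepRow(tuple(minsups), patterns))
    return SweepReport(report.condition_id, tuple(merged))


# ---------------------------------------------------------------------------
# Tallies
# ---------------------------------------------------------------------------


def tally_sizes(report: SweepReport) -> dict[float, dict[int, int]]:
    """Per support level, counts of reported patterns grouped by element count.

    Collapsed rows contribute the same tally to each of their levels.
    Levels with no reported pattern map to an empty tally.
    """
    out: dict[float, dict[int, int]] = {}
    for row in report.rows:
        tally: dict[int, int] = {}
        for pattern, _ in row.patterns:
            tally[pattern.size] = tally.get(pattern.size, 0) + 1
        for minsup in row.minsups:
            out[minsup] = dict(tally)
    return out


def total_patterns(report: SweepReport) -> int:
    """Number of distinct patterns reported across all levels."""
    return len({pattern.elements for pattern, _ in report.all_patterns()})


def behavior_coverage(
    reports: Union[SweepReport, Iterable[SweepReport]],
    ethogram: Ethogram | None = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Partition the ethogram into codes that do / do not appear in reports."""
    eth = ethogram if ethogram is not None else load_default_ethogram()
    if isinstance(reports, SweepReport):
        reports = [reports]
    used: set[str] = set()
    for report in reports:
        for pattern, _ in report.all_patterns():
            used |= pattern.codes
    return frozenset(used), frozenset(eth.codes) - frozenset(used)


def max_reported_size(reports: Union[SweepReport, Iterable[SweepReport]]) -> int:
    """Maximum element count across reported patterns (0 for empty reports)."""
    if isinstance(reports, SweepReport):
        reports = [reports]
    sizes = [pattern.size for report in reports for pattern, _ in report.all_patterns()]
    return max(sizes, default=0)


# ---------------------------------------------------------------------------
# Rendering and fixtures
# ---------------------------------------------------------------------------


def _size_summary(patterns: tuple[ReportedPattern, ...]) -> str:
    tally: dict[int, int] = {}
    for pattern, _ in patterns:
        tally[pattern.size] = tally.get(pattern.size, 0) + 1
    return ", ".join(f"{n} size {s}" for s, n in sorted(tally.items())) or "None"


def format_report(report: SweepReport, collapse: bool = True) -> str:
    """Plain-text table: MinSupport | Sequence Number | Sequence columns."""
    shown = collapse_rows(report) if collapse else report
    lines = []
    if report.condition_id:
        lines.append(f"Condition: {report.condition_id}")
    lines.append("MinSupport\tSequence Number\tSequence")
    for row in shown.rows:
        levels = ", ".join(f"{m:g}" for m in row.minsups)
        if row.patterns:
            pats = "; ".join(p.notation(c) for p, c in row.patterns)
            lines.append(f"{levels}\t{_size_summary(row.patterns)}\t{pats}")
        else:
            lines.append(f"{levels}\tNone\t")
    return "\n".join(lines) + "\n"


def report_to_json(report: SweepReport, seed: int | None = None) -> str:
    doc = {
        "condition": report.condition_id,
        "rows": [
            {
                "minsups": list(row.minsups),
                "patterns": [
                    {"pattern": p.notation(), "size": p.size, "item_count": p.item_count, "n": c}
                    for p, c in row.patterns
                ],
            }
            for row in report.rows
        ],
    }
    if seed is not None:
        doc["seed"] = seed
    return json.dumps(doc, indent=2)


def _parse_table_text(text: str, condition_id: str, ethogram: Ethogram | None) -> SweepReport:
    rows: list[SweepRow] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        levels = tuple(float(x) for x in parts[0].split(","))
        cell = parts[1].strip() if len(parts) > 1 else ""
        if not cell or cell == "None":
            rows.append(SweepRow(levels, ()))
            continue
        patterns = tuple(
            parse_pattern_notation(chunk, ethogram)
            for chunk in (c.strip() for c in cell.split(";"))
            if chunk
        )
        rows.append(SweepRow(levels, patterns))
    return SweepReport(condition_id, tuple(rows))


def load_reference_table(
    condition: str, ethogram: Ethogram | None = None
) -> SweepReport:
    """Load one of the four packaged reference sweep tables.

    ``condition`` is one of :data:`REFERENCE_CONDITIONS`. The tables are
    verbatim transcriptions of published sweep results; they are treated as
    data, not as output of this engine (see docs/methods.md on matching
    semantics), so no mining invariants are enforced on them.
    """
    if condition not in REFERENCE_CONDITIONS:
        raise KeyError(
            f"unknown condition {condition!r}; expected one of {REFERENCE_CONDITIONS}"
        )
    text = (resources.files("broilerseq") / "data" / f"{condition}.tsv").read_text(
        encoding="utf-8"
    )
    return _parse_table_text(text, condition, ethogram)


def load_table_file(
    path: str | Path, condition_id: str = "", ethogram: Ethogram | None = None
) -> SweepReport:
    """Parse an external sweep-table file in the packaged fixture format."""
    return _parse_table_text(Path(path).read_text(encoding="utf-8"), condition_id, ethogram)
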