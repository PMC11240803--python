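"""The broiler-chicken ethogram: a 13-behavior vocabulary.

The registry maps short case-sensitive acronyms (``Ld``, ``P``, ``F``, ...)
to named, described behavior classes. Acronyms are the canonical identifiers
throughout the package — files, mined patterns and reports all use them;
full names are display-only. One behavior (``Ex``, explore) is only possible
in pens with enrichment objects (perch, sandbox, hanging rings) and is
flagged ``enriched_only``.

Registry insertion order is the canonical behavior order used for
deterministic sorting of mined output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import yaml

from .errors import EnvironmentViolationError, SchemaError, UnknownCodeError

__all__ = [
    "BehaviorEntry",
    "Ethogram",
    "load_default_ethogram",
    "load_ethogram",
    "validate_code",
]


@dataclass(frozen=True)
class BehaviorEntry:
    """One behavior class: acronym, display name, description, environment flag."""

    acronym: str
    name: str
    description: str
    enriched_only: bool = False

    def __post_init__(self) -> None:
        if not (1 <= len(self.acronym) <= 2):
            raise ValueError(f"acronym must be 1-2 characters, got {self.acronym!r}")


class Ethogram:
    """An ordered, immutable registry of behavior entries keyed by acronym."""

    def __init__(self, entries: Iterable[BehaviorEntry]):
        self._entries: dict[str, BehaviorEntry] = {}
        for entry in entries:
            if entry.acronym in self._entries:
                raise ValueError(f"duplicate acronym {entry.acronym!r}")
            self._entries[entry.acronym] = entry
        self._order = {code: i for i, code in enumerate(self._entries)}

    @property
    def codes(self) -> tuple[str, ...]:
        """Acronyms in canonical (registry) order."""
        return tuple(self._entries)

    @property
    def entries(self) -> tuple[BehaviorEntry, ...]:
        return tuple(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, code: object) -> bool:
        return code in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __getitem__(self, code: str) -> BehaviorEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise UnknownCodeError(f"unknown behavior code {code!r}") from None

    def index(self, code: str) -> int:
        """Position of ``code`` in canonical order; raises for unknown codes."""
        if code not in self._order:
            raise UnknownCodeError(f"unknown behavior code {code!r}")
        return self._order[code]

    def enriched_only_codes(self) -> tuple[str, ...]:
        return tuple(c for c, e in self._entries.items() if e.enriched_only)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ethogram):
            return NotImplemented
        return self.entries == other.entries

    def __repr__(self) -> str:
        return f"Ethogram({', '.join(self.codes)})"


# Descriptions are short paraphrases of the standard broiler ethogram
# definitions used in climate-chamber welfare studies.
_DEFAULT_ENTRIES: tuple[BehaviorEntry, ...] = (
    BehaviorEntry("Ld", "Lying down", "Resting with the ventral body on the litter, legs folded, eyes open or closed."),
    BehaviorEntry("P", "Preening", "Pecking or nibbling its own feathers while sitting or standing."),
    BehaviorEntry("F", "Forage", "Pecking and scratching at the litter substrate with the neck extended, sitting or standing."),
    BehaviorEntry("W", "Walk", "Taking at least two steps without pecking at the ground."),
    BehaviorEntry("Db", "Dust bathing", "Lying on the litter tossing substrate over the back and wings, ruffling the feathers."),
    BehaviorEntry("Wf", "Wing flap", "Flapping both wings repeatedly."),
    BehaviorEntry("Sf", "Shake feathers", "Ruffling and shaking the feathers of the whole body."),
    BehaviorEntry("E", "Eat", "Head inside the feeder, including small movements around its rim."),
    BehaviorEntry("D", "Drink", "Beak in contact with the drinker, including small movements around it."),
    BehaviorEntry("R", "Run", "Fast locomotion propelled by the legs."),
    BehaviorEntry("St", "Stretching", "Extending one or both wings or legs, then returning to the resting posture."),
    BehaviorEntry("Ll", "Lying laterally", "Lying on the side with a leg and/or wing extended; a heat-dissipation posture."),
    BehaviorEntry("Ex", "Explore", "Interacting with enrichment objects (perch, sandbox, hanging rings).", enriched_only=True),
)

_DEFAULT = Ethogram(_DEFAULT_ENTRIES)


def load_default_ethogram() -> Ethogram:
    """Return the embedded 13-behavior broiler registry."""
    return _DEFAULT


def load_ethogram(path: str | Path) -> Ethogram:
    """Load an ethogram override from a YAML or CSV file.

    CSV columns / YAML mapping keys: ``acronym``, ``name``, ``description``,
    ``enriched_only``. Intended for reuse with other species or coding
    schemes; the default registry stays embedded.
    """
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, list):
            raise SchemaError(f"{path}: expected a YAML list of behavior entries")
        records = raw
    else:
        with open(path, newline="") as fh:
            records = list(csv.DictReader(fh))
    entries = []
    bad_rows: list[int] = []
    for i, rec in enumerate(records, start=1):
        try:
            flag = rec.get("enriched_only", False)
            if isinstance(flag, str):
                flag = flag.strip().lower() in {"1", "true", "yes"}
            entries.append(
                BehaviorEntry(rec["acronym"], rec["name"], rec.get("description", ""), bool(flag))
            )
        except (KeyError, TypeError, ValueError):
            bad_rows.append(i)
    if bad_rows:
        raise SchemaError(f"{path}: invalid ethogram entries", rows=bad_rows)
    return Ethogram(entries)


def validate_code(code: str, ethogram: Ethogram | None = None, enriched: bool = True) -> str:
    """Check that ``code`` exists and is permitted in the given environment.

    Returns the code unchanged on success. Raises
    :class:`~broilerseq.errors.UnknownCodeError` for tokens absent from the
    registry and :class:`~broilerseq.errors.EnvironmentViolationError` for
    enriched-only behaviors when ``enriched`` is False.
    """
    eth = ethogram if ethogram is not None else _DEFAULT
    entry = eth[code]  # raises UnknownCodeError
    if entry.enriched_only and not enriched:
        raise EnvironmentViolationError(
            f"behavior {code!r} ({entry.name}) is only possible in an enriched environment"
        )
    return code
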