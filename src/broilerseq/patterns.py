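"""Sequential patterns and their printed notation.

A pattern is an ordered tuple of *elements*; each element is an ordered run
of behavior codes observed within a single analysis window (repeats allowed,
e.g. ``P,F,P``). The printed dialect is ``<{A,B} {C}>`` with an optional
trailing ``(n = k)`` carrier count, and round-trips exactly through
:func:`parse_pattern_notation` / :func:`format_pattern_notation`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import PatternParseError
from .ethogram import Ethogram, load_default_ethogram

__all__ = [
    "Pattern",
    "parse_pattern_notation",
    "format_pattern_notation",
    "canonical_key",
]


@dataclass(frozen=True)
class Pattern:
    """An ordered sequence of ordered behavior-code runs.

    ``size`` counts elements (the reporting convention: a 4-step pattern of
    8 items has size 4); ``item_count`` counts codes across all elements
    (the level variable of the mining loop). Both are exposed because the
    two conventions coexist in the field.
    """

    elements: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        elements = tuple(tuple(el) for el in self.elements)
        object.__setattr__(self, "elements", elements)
        if not elements:
            raise ValueError("a pattern must have at least one element")
        for el in elements:
            if not el:
                raise ValueError("pattern elements must be non-empty")
            for code in el:
                if not isinstance(code, str) or not code:
                    raise ValueError(f"invalid behavior code {code!r}")

    @classmethod
    def of(cls, *elements: Iterable[str]) -> "Pattern":
        """Convenience constructor: ``Pattern.of(["Ld", "P"], ["Ld", "F"])``."""
        return cls(tuple(tuple(el) for el in elements))

    @property
    def size(self) -> int:
        """Number of elements (steps)."""
        return len(self.elements)

    @property
    def item_count(self) -> int:
        """Total number of behavior codes across elements."""
        return sum(len(el) for el in self.elements)

    @property
    def codes(self) -> frozenset[str]:
        """The set of behavior codes appearing anywhere in the pattern."""
        return frozenset(c for el in self.elements for c in el)

    def notation(self, count: int | None = None) -> str:
        return format_pattern_notation(self, count)

    def __str__(self) -> str:
        return self.notation()


_COUNT_RE = re.compile(r"\(\s*n\s*=\s*(\d+)\s*\)\s*$")


def parse_pattern_notation(
    text: str, ethogram: Ethogram | None = None
) -> tuple[Pattern, int | None]:
    """Parse ``"<{Ld,P} {Ld,P,F}> (n = 2)"`` into a pattern and its count.

    The count is ``None`` when no ``(n = k)`` suffix is printed. Raises
    :class:`~broilerseq.errors.PatternParseError` for unbalanced brackets or
    braces, empty elements, or codes absent from the ethogram.
    """
    eth = ethogram if ethogram is not None else load_default_ethogram()
    s = text.strip()
    count: int | None = None
    m = _COUNT_RE.search(s)
    if m:
        count = int(m.group(1))
        s = s[: m.start()].strip()
    if not (s.startswith("<") and s.endswith(">") and len(s) >= 2):
        raise PatternParseError(f"pattern must be enclosed in <...>: {text!r}")
    inner = s[1:-1]
    elements: list[tuple[str, ...]] = []
    i, n = 0, len(inner)
    while i < n:
        ch = inner[i]
        if ch.isspace():
            i += 1
            continue
        if ch != "{":
            raise PatternParseError(f"expected '{{' at position {i} in {text!r}")
        j = inner.find("}", i)
        if j < 0:
            raise PatternParseError(f"unbalanced braces in {text!r}")
        body = inner[i + 1 : j]
        if "{" in body or "<" in body or ">" in body:
            raise PatternParseError(f"malformed element in {text!r}")
        codes = tuple(tok.strip() for tok in body.split(","))
        if any(not c for c in codes):
            raise PatternParseError(f"empty behavior code in {text!r}")
        for c in codes:
            if c not in eth:
                raise PatternParseError(f"unknown behavior code {c!r} in {text!r}")
        elements.append(codes)
        i = j + 1
    if not elements:
        raise PatternParseError(f"pattern has no elements: {text!r}")
    return Pattern(tuple(elements)), count


def format_pattern_notation(pattern: Pattern, count: int | None = None) -> str:
    """Render a pattern in the printed ``<{A,B} {C}>`` dialect."""
    body = " ".join("{" + ",".join(el) + "}" for el in pattern.elements)
    s = f"<{body}>"
    if count is not None:
        s += f" (n = {count})"
    return s


def canonical_key(pattern: Pattern, ethogram: Ethogram | None = None):
    """Deterministic sort key: item count, then size, then ethogram order.

    Codes outside the ethogram (possible with overrides) sort after known
    codes, lexicographically.
    """
    eth = ethogram if ethogram is not None else load_default_ethogram()

    def code_key(c: str) -> tuple[int, str]:
        return (eth.index(c), "") if c in eth else (len(eth), c)

    return (
        pattern.item_count,
        pattern.size,
        tuple(tuple(code_key(c) for c in el) for el in pattern.elements),
    )


def sort_patterns(patterns: Sequence[Pattern], ethogram: Ethogram | None = None) -> list[Pattern]:
    eth = ethogram if ethogram is not None else load_default_ethogram()
    return sorted(patterns, key=lambda p: canonical_key(p, eth))
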