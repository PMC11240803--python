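"""The GSP mining engine: containment, support, and level-wise mining.

Semantics
---------
* A pattern *element* matches a window when its codes embed into the
  window's codes as an order-preserving, multiplicity-respecting (not
  necessarily contiguous) subsequence.
* A *pattern* is contained in a broiler's sequence when its elements map to
  strictly increasing windows, each matching as above — the transaction
  semantics of classic GSP: items of one element must co-occur within a
  single transaction.
* Support is the fraction of database sequences (broilers) containing the
  pattern; each broiler counts once regardless of how many embeddings
  exist. A pattern is frequent when ``support >= minsup`` (closed
  comparison, so a 2-of-10 pattern is frequent at the 20% threshold).

Mining is level-wise on *total item count*: frequent single items seed the
GSP join, each pass grows candidates by one item, prunes candidates with an
infrequent one-item-deletion subpattern (the Apriori property), counts
supports, and stops when a pass yields nothing. Because observed window
elements never contain adjacent repeats of one code (the merge rule of
windowing), the mined pattern space excludes such elements too; the
brute-force oracle enumerates exactly the same space by depth-first
extension, giving an independent completeness check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import (
    BudgetExceededError,
    EmptyDatabaseError,
    InvalidMinsupError,
    MixedSizeError,
)
from .ethogram import Ethogram, load_default_ethogram
from .patterns import Pattern, canonical_key
from .sequence_db import BroilerSequence, SequenceDatabase

__all__ = [
    "FrequentPattern",
    "element_contained",
    "contains",
    "pattern_contains",
    "support",
    "generate_candidates",
    "mine",
    "brute_force_mine",
]


@dataclass(frozen=True)
class FrequentPattern:
    """A pattern with its support count (number of SIDs) and fraction."""

    pattern: Pattern
    support_count: int
    support: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.support <= 1.0):
            raise ValueError(f"support must lie in [0, 1], got {self.support}")

    def notation(self) -> str:
        return self.pattern.notation(self.support_count)


def element_contained(p: Sequence[str], w: Sequence[str]) -> bool:
    """True iff ``p`` embeds into ``w`` as an ordered subsequence."""
    it = iter(w)
    return all(code in it for code in p)


def contains(seq: BroilerSequence, pattern: Pattern) -> bool:
    """True iff the pattern's elements map to strictly increasing windows.

    Greedy earliest-window matching is exact here: matching an element to
    the first feasible window never excludes a later embedding.
    """
    return _embeds(pattern.elements, seq.elements)


def pattern_contains(container: Pattern, sub: Pattern) -> bool:
    """True iff ``sub`` is a (not necessarily proper) subpattern of ``container``."""
    return _embeds(sub.elements, container.elements)


def _embeds(
    elements: Sequence[Sequence[str]], windows: Sequence[Sequence[str]]
) -> bool:
    wi = 0
    for el in elements:
        while wi < len(windows) and not element_contained(el, windows[wi]):
            wi += 1
        if wi == len(windows):
            return False
        wi += 1
    return True


def _count(pattern: Pattern, db: SequenceDatabase) -> int:
    return sum(1 for seq in db if contains(seq, pattern))


def support(pattern: Pattern, db: SequenceDatabase) -> FrequentPattern:
    """Support of ``pattern``: distinct containing SIDs over database size."""
    if db.n < 1:
        raise EmptyDatabaseError("support is undefined on an empty database")
    cnt = _count(pattern, db)
    return FrequentPattern(pattern, cnt, cnt / db.n)


# ---------------------------------------------------------------------------
# Candidate generation (GSP join + Apriori pruning)
# ---------------------------------------------------------------------------


def _drop_first(els: tuple[tuple[str, ...], ...]) -> tuple[tuple[str, ...], ...]:
    head = els[0][1:]
    return ((head,) + els[1:]) if head else els[1:]


def _drop_last(els: tuple[tuple[str, ...], ...]) -> tuple[tuple[str, ...], ...]:
    tail = els[-1][:-1]
    return (els[:-1] + (tail,)) if tail else els[:-1]


def _one_item_deletions(els: tuple[tuple[str, ...], ...]):
    for i, el in enumerate(els):
        for j in range(len(el)):
            rest = el[:j] + el[j + 1 :]
            if rest:
                yield els[:i] + (rest,) + els[i + 1 :]
            elif len(els) > 1:
                yield els[:i] + els[i + 1 :]


def _has_adjacent_repeat(els: Iterable[Sequence[str]]) -> bool:
    return any(el[i] == el[i + 1] for el in els for i in range(len(el) - 1))


def generate_candidates(frequent_k: Sequence[Pattern]) -> list[Pattern]:
    """Grow (k+1)-item candidates from the frequent k-item seed set.

    Join step: ``s1`` joins ``s2`` when dropping s1's first item equals
    dropping s2's last item; the joined pattern appends s2's last item —
    merged into the final element when it sat inside s2's final element,
    as a new element when it stood alone. For k = 1 every ordered pair of
    frequent items yields both structures. Prune step: any candidate with
    an infrequent one-item-deletion subpattern is removed (deletions that
    would create an adjacent in-element repeat are outside the mined space
    and are skipped, not required).
    """
    pats = list(frequent_k)
    if not pats:
        return []
    sizes = {p.item_count for p in pats}
    if len(sizes) != 1:
        raise MixedSizeError(f"seed patterns have mixed item counts {sorted(sizes)}")
    k = sizes.pop()
    freq_set = {p.elements for p in pats}
    raw: set[tuple[tuple[str, ...], ...]] = set()
    if k == 1:
        codes = [p.elements[0][0] for p in pats]
        for x in codes:
            for y in codes:
                raw.add(((x,), (y,)))
                if x != y:
                    raw.add(((x, y),))
    else:
        by_drop_first: dict[tuple, list[tuple]] = {}
        for p in pats:
            by_drop_first.setdefault(_drop_first(p.elements), []).append(p.elements)
        for p2 in pats:
            s2 = p2.elements
            for s1 in by_drop_first.get(_drop_last(s2), ()):
                last_item = s2[-1][-1]
                if len(s2[-1]) == 1:
                    raw.add(s1 + ((last_item,),))
                else:
                    raw.add(s1[:-1] + (s1[-1] + (last_item,),))

    out: list[Pattern] = []
    for els in raw:
        if _has_adjacent_repeat(els):
            continue  # windowed data merges adjacent repeats; never match data verbatim
        if any(
            sub not in freq_set
            for sub in _one_item_deletions(els)
            if not _has_adjacent_repeat(sub)
        ):
            continue
        out.append(Pattern(els))
    out.sort(key=canonical_key)
    return out


# ---------------------------------------------------------------------------
# Mining
# ---------------------------------------------------------------------------


def _check_mining_args(db: SequenceDatabase, minsup: float) -> None:
    if db.n < 1:
        raise EmptyDatabaseError("cannot mine an empty database")
    if not (0.0 < minsup <= 1.0):
        raise InvalidMinsupError(f"minsup must lie in (0, 1], got {minsup}")


def mine(
    db: SequenceDatabase,
    minsup: float,
    *,
    ethogram: Ethogram | None = None,
    max_items: int | None = None,
) -> list[FrequentPattern]:
    """All frequent patterns at ``minsup``, in canonical order.

    The level-wise loop terminates on its own by the item count of the
    longest data sequence; ``max_items`` optionally caps it earlier for
    exploratory runs on dense data.
    """
    _check_mining_args(db, minsup)
    eth = ethogram if ethogram is not None else load_default_ethogram()
    threshold = minsup * db.n - 1e-9

    level: list[FrequentPattern] = []
    for code in sorted(db.alphabet(), key=lambda c: canonical_key(Pattern.of([c]), eth)):
        p = Pattern.of([code])
        cnt = _count(p, db)
        if cnt >= threshold:
            level.append(FrequentPattern(p, cnt, cnt / db.n))
    results = list(level)

    while level:
        if max_items is not None and level[0].pattern.item_count >= max_items:
            break
        candidates = generate_candidates([fp.pattern for fp in level])
        nxt: list[FrequentPattern] = []
        for p in candidates:
            cnt = _count(p, db)
            if cnt >= threshold:
                nxt.append(FrequentPattern(p, cnt, cnt / db.n))
        level = nxt
        results.extend(nxt)

    results.sort(key=lambda fp: canonical_key(fp.pattern, eth))
    return results


def brute_force_mine(
    db: SequenceDatabase,
    minsup: float,
    max_items: int,
    *,
    budget: int = 250_000,
    ethogram: Ethogram | None = None,
) -> list[FrequentPattern]:
    """Exhaustive oracle: depth-first enumeration of the pattern space.

    Grows every pattern by appending one item at a time (either opening a
    new element or extending the last one with a different code) and
    recurses only below frequent prefixes — exact, because dropping
    trailing items never lowers support. Intended for small fixtures only:
    at most 12 sequences, 6 windows per sequence, a 6-code alphabet and
    ``max_items <= 5``; anything larger (or more than ``budget`` support
    evaluations) raises :class:`~broilerseq.errors.BudgetExceededError`.
    """
    _check_mining_args(db, minsup)
    eth = ethogram if ethogram is not None else load_default_ethogram()
    alphabet = db.alphabet()
    if (
        db.n > 12
        or any(len(s.elements) > 6 for s in db)
        or len(alphabet) > 6
        or max_items > 5
        or max_items < 1
    ):
        raise BudgetExceededError(
            "brute-force enumeration bound exceeded: limits are 12 sequences, "
            "6 windows, 6 codes, max_items in [1, 5] "
            f"(got n={db.n}, windows={max((len(s.elements) for s in db), default=0)}, "
            f"alphabet={len(alphabet)}, max_items={max_items})"
        )
    threshold = minsup * db.n - 1e-9
    codes = sorted(alphabet, key=lambda c: canonical_key(Pattern.of([c]), eth))
    results: list[FrequentPattern] = []
    evals = 0

    def evaluate(els: tuple[tuple[str, ...], ...]) -> int:
        nonlocal evals
        evals += 1
        if evals > budget:
            raise BudgetExceededError(f"brute-force budget of {budget} evaluations exceeded")
        return _count(Pattern(els), db)

    def grow(els: tuple[tuple[str, ...], ...], items: int) -> None:
        if items >= max_items:
            return
        for c in codes:
            extensions = [els + ((c,),)]
            if els[-1][-1] != c:
                extensions.append(els[:-1] + (els[-1] + (c,),))
            for q in extensions:
                cnt = evaluate(q)
                if cnt >= threshold:
                    results.append(FrequentPattern(Pattern(q), cnt, cnt / db.n))
                    grow(q, items + 1)

    for c in codes:
        els = ((c,),)
        cnt = evaluate(els)
        if cnt >= threshold:
            results.append(FrequentPattern(Pattern(els), cnt, cnt / db.n))
            grow(els, 1)

    results.sort(key=lambda fp: canonical_key(fp.pattern, eth))
    return results
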