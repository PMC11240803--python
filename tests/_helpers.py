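"""Shared test utilities: seeded random databases for oracle equivalence."""

import random

from broilerseq import BroilerSequence, build_database

ALPHABET = ("Ld", "P", "F", "W", "E", "D")  # six codes: within the oracle's bounds


def random_database(
    rng: random.Random,
    *,
    max_seqs: int = 10,
    max_windows: int = 6,
    alphabet=ALPHABET,
    max_items_per_seq: int = 4,
):
    """A small random database obeying the windowed-data model.

    Window elements never contain adjacent repeats of one code (windowing
    merges those), and each sequence carries at most ``max_items_per_seq``
    codes so exhaustive enumeration stays cheap.
    """
    n = rng.randint(2, max_seqs)
    seqs = []
    for i in range(n):
        n_windows = rng.randint(1, max_windows)
        budget = max_items_per_seq
        elements = []
        for _ in range(n_windows):
            m = rng.randint(0, min(2, budget))
            codes = []
            prev = None
            for _ in range(m):
                c = rng.choice(alphabet)
                if c != prev:
                    codes.append(c)
                    prev = c
            budget -= len(codes)
            elements.append(tuple(codes))
        seqs.append(BroilerSequence(f"b{i}", tuple(elements)))
    return build_database(seqs)


def one_item_deletions(elements):
    """All one-item-deletion subpatterns of an element tuple."""
    for i, el in enumerate(elements):
        for j in range(len(el)):
            rest = el[:j] + el[j + 1 :]
            if rest:
                yield elements[:i] + (rest,) + elements[i + 1 :]
            elif len(elements) > 1:
                yield elements[:i] + elements[i + 1 :]
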