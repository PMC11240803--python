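import random

import pytest
from hypothesis import given, strategies as st

from broilerseq import (
    Bout,
    BroilerSequence,
    DuplicateSidError,
    OverlapError,
    Pattern,
    PatternParseError,
    SchemaError,
    WindowRangeError,
    bouts_to_windows,
    build_database,
    format_pattern_notation,
    parse_pattern_notation,
    read_bout_csv,
    read_db_text,
    sequence_size,
    write_bout_csv,
    write_db_text,
)

CODES = ["Ld", "P", "F", "W", "E", "D", "St", "Ll"]


def _bout(code, onset, dur, *, broiler="b1", window=0):
    return Bout(broiler, "test", window, onset, dur, code)


class TestWindowing:
    def test_short_bouts_dropped_and_same_code_runs_merged(self):
        bouts = [_bout("Ld", 0, 120), _bout("P", 120, 8), _bout("Ld", 128, 60)]
        (seq,) = bouts_to_windows(bouts, n_windows=1)
        assert seq.elements == (("Ld",),)

    def test_chronological_order_with_repeats_kept(self):
        bouts = [_bout("Ld", 0, 60), _bout("P", 60, 30), _bout("F", 90, 20), _bout("P", 110, 40)]
        (seq,) = bouts_to_windows(bouts, n_windows=1)
        assert seq.elements == (("Ld", "P", "F", "P"),)

    def test_empty_bout_set_gives_no_sequences(self):
        assert bouts_to_windows([], n_windows=14) == []

    def test_broiler_without_qualifying_bouts_keeps_empty_windows(self):
        (seq,) = bouts_to_windows([_bout("P", 0, 9)], n_windows=14)
        assert len(seq.elements) == 14
        assert all(el == () for el in seq.elements)

    def test_boundary_crossing_bout_truncated_at_ingestion(self):
        # 295 s onset leaves 5 s in a 300 s window: below the floor, dropped.
        (seq,) = bouts_to_windows([_bout("Ld", 295, 60)], n_windows=1)
        assert seq.elements == ((),)
        # 280 s onset leaves 20 s: qualifies.
        (seq,) = bouts_to_windows([_bout("Ld", 280, 60)], n_windows=1)
        assert seq.elements == (("Ld",),)

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(OverlapError):
            bouts_to_windows([_bout("Ld", 0, 60), _bout("P", 30, 40)], n_windows=1)

    def test_window_index_out_of_range_rejected(self):
        with pytest.raises(WindowRangeError):
            bouts_to_windows([_bout("Ld", 0, 60, window=3)], n_windows=3)

    def test_condition_day_pooling_refused(self):
        bouts = [
            Bout("b1", "comfort", 0, 0, 60, "Ld", day=21),
            Bout("b1", "heat", 1, 0, 60, "Ld", day=22),
        ]
        with pytest.raises(SchemaError):
            bouts_to_windows(bouts, n_windows=2)
        assert len(bouts_to_windows(bouts, n_windows=2, allow_mixed=True)) == 1

    def test_windowing_is_idempotent(self):
        """Re-expressing windowed output as bouts and windowing again is a no-op."""
        rng = random.Random(4221)
        for _ in range(25):
            bouts, t, w = [], 0.0, 0
            for _ in range(rng.randint(1, 40)):
                dur = rng.choice([4, 8, 10, 15, 30, 60])
                if t + dur > 300:
                    w, t = w + 1, 0.0
                if w >= 3:
                    break
                bouts.append(_bout(rng.choice(CODES), t, dur, window=w))
                t += dur
            (seq,) = bouts_to_windows(bouts, n_windows=3)
            rebouts = [
                _bout(code, i * 10.0, 10.0, window=wi)
                for wi, el in enumerate(seq.elements)
                for i, code in enumerate(el)
            ]
            (again,) = bouts_to_windows(rebouts, n_windows=3) if rebouts else (seq,)
            assert again.elements == seq.elements

    def test_element_order_follows_bout_onset_order(self):
        rng = random.Random(99)
        for _ in range(20):
            onsets, t = [], 0.0
            codes = []
            while t < 240:
                dur = rng.choice([10, 20, 30])
                codes.append(rng.choice(CODES))
                onsets.append((t, dur))
                t += dur
            bouts = [_bout(c, o, d) for c, (o, d) in zip(codes, onsets)]
            (seq,) = bouts_to_windows(bouts, n_windows=1)
            # the element is the onset-ordered code list with adjacent repeats merged
            expected = [c for i, c in enumerate(codes) if i == 0 or c != codes[i - 1]]
            assert list(seq.elements[0]) == expected


class TestDatabase:
    def test_worked_example_shape(self, example_db):
        assert example_db.n == 2
        assert example_db["broiler_1"].elements == (("E",), ("W",), ("D",))
        assert example_db["broiler_2"].elements == (("Ld",), ("P",))

    def test_single_empty_sequence_allowed(self):
        db = build_database([BroilerSequence("solo", ((),))])
        assert db.n == 1

    def test_duplicate_sid_rejected(self):
        seqs = [BroilerSequence("b", (("Ld",),)), BroilerSequence("b", (("P",),))]
        with pytest.raises(DuplicateSidError):
            build_database(seqs)

    def test_sequence_sizes_of_worked_example(self, example_db):
        assert sequence_size(example_db["broiler_1"]) == 3
        assert sequence_size(example_db["broiler_2"]) == 2

    def test_pattern_size_counts_steps_not_items(self):
        pattern = Pattern.of(["P", "F", "P"], ["Ld", "P"], ["Ld", "F"], ["Ld", "P"])
        assert sequence_size(pattern) == 4
        assert pattern.item_count == 9


class TestPatternNotation:
    @pytest.mark.parametrize(
        "text,sizes,count",
        [
            ("<{Ld,P} {Ld,P,F,P}> (n = 3)", (2, 4), 3),
            ("<{E,W,F}>", (3,), None),
            ("<{P,Ld} {Ld, P,F}>", (2, 3), None),  # stray space inside an element
        ],
    )
    def test_parse_examples(self, text, sizes, count):
        pattern, n = parse_pattern_notation(text)
        assert tuple(len(el) for el in pattern.elements) == sizes
        assert n == count

    @pytest.mark.parametrize("bad", ["<{Ld,P>", "<Ld,P}>", "<{}>", "<{Zz}>", "{Ld}", "<>"])
    def test_malformed_notation_rejected(self, bad):
        with pytest.raises(PatternParseError):
            parse_pattern_notation(bad)

    @given(
        st.lists(
            st.lists(st.sampled_from(CODES), min_size=1, max_size=4),
            min_size=1,
            max_size=4,
        )
    )
    def test_parse_inverts_format(self, elements):
        pattern = Pattern.of(*elements)
        for count in (None, 2):
            parsed, n = parse_pattern_notation(format_pattern_notation(pattern, count))
            assert parsed == pattern and n == count


class TestTextIO:
    def test_bout_csv_roundtrip(self, tmp_path):
        bouts = [
            Bout("b1", "comfort", 0, 0.0, 30.0, "Ld", day=21),
            Bout("b1", "comfort", 1, 12.5, 9.0, "P", day=21),  # short bout accepted at read
            Bout("b2", "comfort", 0, 5.0, 60.0, "E", day=21),
        ]
        path = tmp_path / "bouts.csv"
        write_bout_csv(bouts, path, seed=3)
        assert read_bout_csv(path) == bouts

    def test_db_text_roundtrip_preserves_empty_windows(self, tmp_path, example_db):
        path = tmp_path / "db.txt"
        write_db_text(example_db, path)
        assert read_db_text(path) == example_db
        db2 = build_database([BroilerSequence("b1", (("Ld",), (), ("P",)))])
        write_db_text(db2, path)
        assert read_db_text(path) == db2

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("broiler_id,condition,day,window_index,onset_s,duration_s\nb1,c,21,0,0,30\n")
        with pytest.raises(SchemaError, match="behavior"):
            read_bout_csv(path)

    def test_bad_rows_reported_by_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "broiler_id,condition,day,window_index,onset_s,duration_s,behavior\n"
            "b1,c,21,0,0,30,Ld\n"
            "b1,c,21,0,xx,30,Ld\n"
            "b1,c,21,1,0,30,Zz\n"
        )
        with pytest.raises(SchemaError) as err:
            read_bout_csv(path)
        assert err.value.rows == [3, 4]
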