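"""Cell-record validation, table I/O, and cross-classification."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from xcifish import (
    ContingencyTable2x2,
    EscapeCounts,
    FormatError,
    Stratum,
    ValidationError,
    cross_classify,
    escape_counts,
    read_cell_table,
    read_contingency_tables,
    write_cell_table,
    write_contingency_tables,
)
from .conftest import make_cell


class TestCellScoreInvariants:
    def test_xy_cell_cannot_carry_xi_focus(self):
        with pytest.raises(ValidationError, match="Xi"):
            make_cell(group="XY", foci7=1, xi7=True)

    def test_xy_cell_cannot_be_biallelic(self):
        with pytest.raises(ValidationError, match="single X"):
            make_cell(group="XY", foci7=2)

    def test_xa_attribution_requires_detected_marker(self):
        with pytest.raises(ValidationError, match="marker"):
            make_cell(marker=False, foci7=1, xa7=True)

    def test_xa_and_xi_together_require_two_foci(self):
        with pytest.raises(ValidationError, match="two foci"):
            make_cell(foci7=1, xa7=True, xi7=True)
        make_cell(foci7=2, xa7=True, xi7=True)  # valid

    def test_attribution_flag_requires_a_focus(self):
        with pytest.raises(ValidationError, match="no focus"):
            make_cell(foci8=0, xa8=True)

    def test_lone_focus_without_marker_cannot_be_xi(self):
        with pytest.raises(ValidationError, match="patent Xa"):
            make_cell(marker=False, foci7=1, xi7=True)

    def test_more_than_two_foci_rejected(self):
        with pytest.raises(ValidationError, match="0..2"):
            make_cell(foci7=3)


class TestCellTableIO:
    def test_round_trip_preserves_records_and_order(self, tmp_path):
        cells = [
            make_cell(donor="dA", foci7=2, foci8=1, xa7=True, xi7=True, xa8=True),
            make_cell(donor="dA", group="XY", marker=False, foci8=1),
            make_cell(donor="dB", foci7=0, foci8=0, marker=False),
        ]
        path = tmp_path / "cells.tsv"
        write_cell_table(cells, path)
        assert read_cell_table(path) == cells

    def test_header_only_file_yields_empty_collection(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_cell_table([], path)
        assert read_cell_table(path) == []

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("donor_id\tgroup\nd1\tXX\n")
        with pytest.raises(FormatError, match="tlr7_foci"):
            read_cell_table(path)

    def test_invariant_violation_reports_row_index(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "donor_id\tgroup\tcell_type\txa_marker\ttlr7_foci\ttlr8_foci\t"
            "tlr7_xa\ttlr8_xa\ttlr7_xi\ttlr8_xi\n"
            "d1\tXX\tmonocyte\t1\t1\t0\t1\t0\t0\t0\n"
            "d1\tXY\tmonocyte\t1\t1\t0\t0\t0\t1\t0\n"
        )
        with pytest.raises(ValidationError, match="row 1"):
            read_cell_table(path)


class TestCrossClassify:
    def test_one_cell_per_category(self, four_pattern_cells):
        t = cross_classify(four_pattern_cells, Stratum.ANY_X)
        assert t.as_tuple() == (1, 1, 1, 1)

    def test_no_marker_cells_give_zero_xa_table(self):
        cells = [make_cell(marker=False, foci7=1) for _ in range(5)]
        t = cross_classify(cells, Stratum.XA_ONLY)
        assert t.as_tuple() == (0, 0, 0, 0)

    def test_empty_input_gives_zero_table(self):
        assert cross_classify([], Stratum.ANY_X).n_total == 0

    def test_mixed_donors_rejected(self):
        cells = [make_cell(donor="d1"), make_cell(donor="d2")]
        with pytest.raises(ValidationError, match="single donor"):
            cross_classify(cells, Stratum.ANY_X)

    def test_matches_independent_tally_on_20_cell_fixture(self):
        rng = random.Random(42)
        cells = []
        for _ in range(20):
            marker = rng.random() < 0.5
            f7 = rng.randint(0, 2)
            f8 = rng.randint(0, 2)
            xa7 = marker and f7 >= 1 and rng.random() < 0.7
            xa8 = marker and f8 >= 1 and rng.random() < 0.7
            xi7 = f7 == 2 or (marker and f7 == 1 and not xa7)
            xi8 = f8 == 2 or (marker and f8 == 1 and not xa8)
            cells.append(
                make_cell(marker=marker, foci7=f7, foci8=f8,
                          xa7=xa7, xa8=xa8, xi7=xi7, xi8=xi8)
            )
        # independent brute-force tally straight off the attributes
        for stratum, pos7, pos8, keep in [
            (Stratum.ANY_X, lambda c: c.tlr7_foci >= 1,
             lambda c: c.tlr8_foci >= 1, lambda c: True),
            (Stratum.XA_ONLY, lambda c: c.tlr7_xa, lambda c: c.tlr8_xa,
             lambda c: c.xa_marker_detected),
            (Stratum.XI_ONLY, lambda c: c.tlr7_xi, lambda c: c.tlr8_xi,
             lambda c: True),
        ]:
            kept = [c for c in cells if keep(c)]
            expect = (
                sum(pos7(c) and pos8(c) for c in kept),
                sum(pos8(c) and not pos7(c) for c in kept),
                sum(pos7(c) and not pos8(c) for c in kept),
                sum(not pos7(c) and not pos8(c) for c in kept),
            )
            assert cross_classify(cells, stratum).as_tuple() == expect

    @given(st.permutations(range(12)), st.data())
    def test_permutation_invariant_and_totals(self, order, data):
        base = []
        for i in range(12):
            marker = data.draw(st.booleans(), label=f"marker{i}")
            f7 = data.draw(st.integers(0, 1), label=f"f7_{i}")
            f8 = data.draw(st.integers(0, 1), label=f"f8_{i}")
            base.append(
                make_cell(marker=marker, foci7=f7, foci8=f8,
                          xa7=marker and f7 == 1, xa8=marker and f8 == 1)
            )
        shuffled = [base[i] for i in order]
        for stratum in Stratum:
            assert (cross_classify(base, stratum)
                    == cross_classify(shuffled, stratum))
        assert cross_classify(base, Stratum.ANY_X).n_total == len(base)
        assert cross_classify(base, Stratum.XA_ONLY).n_total == sum(
            c.xa_marker_detected for c in base
        )


class TestEscapeCounts:
    def test_biallelic_xi_only_and_positive_tally(self):
        cells = (
            [make_cell(foci7=2, xa7=True, xi7=True)] * 2
            + [make_cell(foci7=1, xi7=True)] * 1
            + [make_cell(foci7=1, xa7=True)] * 7
        )
        ec = escape_counts(cells, "TLR7")
        assert (ec.n_biallelic, ec.n_xi_only, ec.n_positive_total) == (2, 1, 10)
        assert ec.n_escape == 3

    def test_no_positive_cells(self):
        ec = escape_counts([make_cell() for _ in range(4)], "TLR8")
        assert (ec.n_biallelic, ec.n_xi_only, ec.n_positive_total) == (0, 0, 0)

    def test_xy_donor_rejected(self):
        with pytest.raises(ValidationError, match="XY"):
            escape_counts([make_cell(group="XY")], "TLR7")

    def test_matches_brute_force_on_50_cell_fixture(self):
        rng = random.Random(7)
        cells = []
        for _ in range(50):
            marker = rng.random() < 0.4
            f8 = rng.randint(0, 2)
            xa8 = marker and f8 >= 1 and rng.random() < 0.5
            xi8 = f8 == 2 or (marker and f8 == 1 and not xa8 and rng.random() < 0.5)
            cells.append(make_cell(marker=marker, foci8=f8, xa8=xa8, xi8=xi8))
        ec = escape_counts(cells, "TLR8")
        assert ec.n_biallelic == sum(c.tlr8_foci == 2 for c in cells)
        assert ec.n_xi_only == sum(
            c.tlr8_foci == 1 and c.tlr8_xi for c in cells
        )
        assert ec.n_positive_total == sum(c.tlr8_foci >= 1 for c in cells)

    def test_escape_cannot_exceed_positive(self):
        with pytest.raises(ValidationError, match="outnumber"):
            EscapeCounts("TLR7", 5, 5, 8)


class TestContingencyIO:
    def test_round_trip(self, tmp_path):
        entries = [
            ("d1", Stratum.ANY_X, ContingencyTable2x2(14, 3, 9, 74)),
            ("d2", Stratum.XI_ONLY, ContingencyTable2x2(0, 0, 0, 0)),
        ]
        path = tmp_path / "tables.tsv"
        write_contingency_tables(entries, path)
        assert read_contingency_tables(path) == entries

    def test_written_cells_sum_to_n(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_contingency_tables(
            [("d1", Stratum.ANY_X, ContingencyTable2x2(14, 3, 9, 74))], path
        )
        (_, _, table), = read_contingency_tables(path)
        assert table.n_total == 100

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(-1, 0, 0, 0)
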