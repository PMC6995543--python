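import itertools
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from earlyfold.contingency import (
    AA_ALPHABET,
    CODE_ALPHABET,
    N_CODE4,
    N_SEQ4,
    ContingencyTable,
    WindowPair,
    build_table,
    code4_rank,
    code4_unrank,
    correlation_screen,
    extract_windows,
    large_sample_critical,
    negative_significant,
    pearson_r,
    scale_smaller,
    scale_table,
    seq4_rank,
    seq4_unrank,
    significance,
)
from earlyfold.errors import UndefinedCorrelationError


class TestRanks:
    def test_capacities(self):
        assert N_SEQ4 == 20**4 == 160_000
        assert N_CODE4 == 7**4 == 2401

    def test_bijection_full_sweep(self):
        assert all(seq4_rank(seq4_unrank(i)) == i for i in range(N_SEQ4))
        assert all(code4_rank(code4_unrank(i)) == i for i in range(N_CODE4))

    def test_lexicographic_order(self):
        assert seq4_unrank(0) == "AAAA" and seq4_unrank(N_SEQ4 - 1) == "YYYY"
        assert code4_unrank(0) == "AAAA" and code4_unrank(N_CODE4 - 1) == "GGGG"
        assert seq4_rank("AAAC") == 1 and code4_rank("AAAB") == 1

    def test_invalid_keys(self):
        with pytest.raises(ValueError):
            seq4_rank("AXAA")
        with pytest.raises(ValueError):
            code4_rank("AAAH")


class TestExtractWindows:
    def test_compliant_origin_counts(self):
        pairs = extract_windows("A" * 10, "C" * 10, origin_compliant=True)
        assert len(pairs) == 7
        assert all(p.label == "compliant" for p in pairs)

    def test_straddling_windows_dropped(self):
        # statuses CCCCNNNN: windows 1-4 (C) and 5-8 (N) survive; the
        # straddlers 2-5, 3-6, 4-7 are dropped
        pairs = extract_windows(
            "ACDEFGHI", "ABCDEFGA", statuses="CCCCNNNN", origin_compliant=False
        )
        assert [(p.seq4, p.label) for p in pairs] == [
            ("ACDE", "compliant"),
            ("FGHI", "noncompliant"),
        ]

    def test_too_short_is_empty(self):
        assert extract_windows("ACD", "ABC", origin_compliant=True) == []

    def test_undefined_codes_and_x_dropped(self):
        pairs = extract_windows("ACDEXFGHI", "AAAA-BBBB", origin_compliant=True)
        assert [(p.seq4, p.code4) for p in pairs] == [
            ("ACDE", "AAAA"), ("FGHI", "BBBB")
        ]


class TestTable:
    def test_identical_pairs_aggregate(self):
        pairs = [WindowPair("ACDE", "CCCC", "compliant")] * 5
        table = build_table(pairs, "compliant")
        assert table.counts == {("ACDE", "CCCC"): 5}
        assert table.total == 5

    def test_empty_table(self):
        table = build_table([], "compliant")
        assert table.total == 0 and table.counts == {}

    def test_reduced_alphabet_combinatorics(self):
        pairs = [
            WindowPair("".join(s), "AAAA", "compliant")
            for s in itertools.product("AC", repeat=4)
        ]
        table = build_table(pairs, "compliant")
        assert len(table.occupied_columns()) == 16

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_table([WindowPair("ACDE", "CCCC", "compliant")], "noncompliant")

    def test_column_vector_rank_oracle(self):
        table = build_table([WindowPair("ACDE", "CCCC", "compliant")] * 3, "compliant")
        v = table.column_vector("ACDE")
        assert v.shape == (N_CODE4,)
        # positional arithmetic over the 7-letter alphabet: C=2
        rank = ((2 * 7 + 2) * 7 + 2) * 7 + 2
        assert v[rank] == 3 and v.sum() == 3
        assert np.all(build_table([], "x").column_vector("AAAA") == 0)

    def test_row_vector_and_marginals(self):
        pairs = [
            WindowPair("ACDE", "CCCC", "compliant"),
            WindowPair("ACDE", "AAAA", "compliant"),
            WindowPair("YYYY", "CCCC", "compliant"),
        ]
        table = build_table(pairs, "compliant")
        row = table.row_vector("CCCC")
        assert row.shape == (N_SEQ4,)
        assert row[seq4_rank("ACDE")] == 1 and row[seq4_rank("YYYY")] == 1
        assert table.column_vector("ACDE").sum() == 2

    def test_tsv_round_trip(self, tmp_path):
        pairs = [WindowPair("ACDE", "CCCC", "compliant")] * 4 + [
            WindowPair("MMMM", "GGGG", "compliant")
        ]
        table = build_table(pairs, "compliant")
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = ContingencyTable.from_tsv(path)
        assert back.counts == table.counts and back.total == table.total


class TestScaling:
    def _tables(self, total_small, total_large):
        small = build_table(
            [WindowPair("ACDE", "CCCC", "noncompliant")] * total_small, "noncompliant"
        )
        large = build_table(
            [WindowPair("ACDE", "CCCC", "compliant")] * total_large, "compliant"
        )
        return small, large

    def test_factor_four(self):
        small, large = self._tables(250, 1000)
        scaled, factor = scale_table(small, large)
        assert factor == 4.0
        assert scaled.counts[("ACDE", "CCCC")] == 1000.0
        assert scaled.total == pytest.approx(large.total, abs=1e-9)

    def test_equal_totals_identity(self):
        small, large = self._tables(100, 100)
        scaled, factor = scale_table(small, large)
        assert factor == 1.0 and scaled.counts == small.counts

    def test_scale_smaller_orients_itself(self):
        small, large = self._tables(10, 40)
        a, b, factor = scale_smaller(large, small)
        assert factor == 4.0 and b.total == pytest.approx(a.total)

    def test_empty_rejected(self):
        empty = build_table([], "compliant")
        other = build_table([WindowPair("ACDE", "CCCC", "compliant")], "compliant")
        with pytest.raises(ValueError, match="empty"):
            scale_table(empty, other)


class TestPearson:
    def test_perfect_linear(self):
        assert pearson_r([1, 2, 3, 4], [3, 5, 7, 9]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3, 4], [-1, -2, -3, -4]) == pytest.approx(-1.0)

    def test_hand_evaluation_oracle(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        mx, my = x.mean(), y.mean()
        expect = ((x - mx) * (y - my)).sum() / math.sqrt(
            ((x - mx) ** 2).sum() * ((y - my) ** 2).sum()
        )
        assert pearson_r(x, y) == pytest.approx(expect, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestSignificance:
    def test_zero_r_not_significant(self):
        z, sig = significance(0.0, 100)
        assert z == 0.0 and not sig

    def test_critical_r_at_n_2401_root_oracle(self):
        # minimal |r| declared significant solves r sqrt(2399)/sqrt(1-r^2) = 1.96
        r_crit = brentq(
            lambda r: r * math.sqrt(2399) / math.sqrt(1 - r * r) - 1.96, 1e-9, 0.5
        )
        assert 0.03 < r_crit < 0.05
        assert significance(r_crit * 1.001, 2401)[1]
        assert not significance(r_crit * 0.999, 2401)[1]

    def test_perfect_correlation_significant_by_convention(self):
        z, sig = significance(1.0, 10)
        assert sig and math.isinf(z)

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="insufficient"):
            significance(0.5, 2)

    def test_large_sample_critical_value(self):
        assert round(large_sample_critical(0.05), 2) == 1.96


class TestScreen:
    def _random_tables(self, rng, n_keys=8, m=200):
        keys = set()
        while len(keys) < n_keys:
            keys.add("".join(rng.choice(list(AA_ALPHABET), 4)))
        tc = ContingencyTable(label="compliant")
        tn = ContingencyTable(label="noncompliant")
        for seq in keys:
            p = rng.dirichlet(np.full(40, 0.5))
            cells = rng.choice(N_CODE4, size=40, replace=False)
            for table, size in ((tc, m), (tn, m // 2)):
                counts = rng.multinomial(size, p)
                for cell, cnt in zip(cells, counts):
                    if cnt:
                        table.add(code4=code4_unrank(int(cell)), seq4=seq, weight=cnt)
        return tc, tn

    def test_identical_tables_all_positive(self, rng):
        tc, _ = self._random_tables(rng)
        records = correlation_screen(tc, tc.copy(), mode="columns")
        assert all(r.r == pytest.approx(1.0) for r in records if not math.isnan(r.r))
        assert negative_significant(records) == []

    def test_scaling_does_not_change_verdicts(self, rng):
        tc, tn = self._random_tables(rng)
        plain = correlation_screen(tc, tn, mode="columns")
        sc, sn, _ = scale_smaller(tc, tn)
        scaled = correlation_screen(sc, sn, mode="columns")
        for a, b in zip(plain, scaled):
            assert a.key == b.key and a.significant == b.significant
            if not math.isnan(a.r):
                assert a.r == pytest.approx(b.r, abs=1e-9)

    def test_screen_symmetry(self, rng):
        tc, tn = self._random_tables(rng)
        ab = correlation_screen(tc, tn, mode="columns")
        ba = correlation_screen(tn, tc, mode="columns")
        assert [r.key for r in ab] == [r.key for r in ba]
        for a, b in zip(ab, ba):
            if not math.isnan(a.r):
                assert a.r == pytest.approx(b.r, abs=1e-9)

    def test_joint_nonzero_mode_runs(self, rng):
        tc, tn = self._random_tables(rng)
        records = correlation_screen(tc, tn, mode="columns", cells="joint_nonzero")
        for r in records:
            if not math.isnan(r.r):
                assert r.n <= N_CODE4

    def test_empty_tables_rejected(self):
        with pytest.raises(ValueError, match="nothing to screen"):
            correlation_screen(
                ContingencyTable(label="a"), ContingencyTable(label="b")
            )

    def test_sparse_matches_dense_column_pearson(self, rng):
        tc, tn = self._random_tables(rng, n_keys=3)
        records = {r.key: r for r in correlation_screen(tc, tn, mode="columns")}
        for key in tc.occupied_columns():
            x = tc.column_vector(key)
            y = tn.column_vector(key)
            assert records[key].r == pytest.approx(pearson_r(x, y), abs=1e-9)
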