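"""Flank extraction, repeat overlap counting, interval subtraction and the
Spearman correlation report."""

import numpy as np
import pandas as pd
import pytest
from conftest import spearman_oracle
from hypothesis import given, settings, strategies as st

from numtsome.hsp import HSP
from numtsome.purge import assemble_numts
from numtsome.repeats import (FlankSpec, count_re, flanks, interval_subtract,
                              re_free_subset, spearman_matrix)


def mk_numts(chrom="chr1", start=5000, end=6000, strand="+"):
    h = HSP(0, end - start, chrom, start, end, strand, 95.0, end - start,
            0, 0, 100.0, 1e-30)
    (x,) = assemble_numts([h])
    return x


CHROMS = {"chr1": 100_000}


class TestFlanks:
    def test_plus_strand(self):
        five, three = flanks([mk_numts()], CHROMS, FlankSpec(2000))
        assert five == [("chr1", 3000, 5000)]
        assert three == [("chr1", 6000, 8000)]

    def test_minus_strand_reflected(self):
        five, three = flanks([mk_numts(strand="-")], CHROMS, FlankSpec(2000))
        assert five == [("chr1", 6000, 8000)]
        assert three == [("chr1", 3000, 5000)]

    def test_clipped_at_contig_start(self):
        five, three = flanks([mk_numts(start=500, end=900)], CHROMS,
                             FlankSpec(2000))
        assert five == [("chr1", 0, 500)]
        assert three == [("chr1", 900, 2900)]


class TestCountRe:
    def test_repeat_inside_locus(self):
        x = mk_numts()
        reps = [("chr1", 5200, 5300, "SINE_1", 0, "+")]
        table = count_re([x], reps, CHROMS)
        assert table.loc["numts_locus", "count"] == 1
        assert table.loc["flank_5p", "count"] == 0

    def test_straddling_repeat_counted_in_both_classes(self):
        x = mk_numts()
        reps = [("chr1", 4900, 5100, "LINE_1", 0, "+")]
        table = count_re([x], reps, CHROMS)
        assert table.loc["numts_locus", "count"] == 1
        assert table.loc["flank_5p", "count"] == 1

    def test_normalization_by_numts_count(self):
        xs = [mk_numts(start=5000, end=6000), mk_numts(start=50_000, end=51_000)]
        reps = [("chr1", 5100, 5200, "a", 0, "+"),
                ("chr1", 50_100, 50_200, "b", 0, "+")]
        table = count_re(xs, reps, CHROMS)
        assert table.loc["numts_locus", "per_numts"] == pytest.approx(1.0)

    def test_counts_match_per_base_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            xs = [mk_numts(start=int(s), end=int(s) + 800)
                  for s in rng.integers(3000, 90_000, 4)]
            reps = []
            for i in range(20):
                s = int(rng.integers(0, 99_000))
                reps.append(("chr1", s, s + int(rng.integers(50, 900)),
                             f"r{i}", 0, "+"))
            table = count_re(xs, reps, CHROMS)
            five, three = flanks(xs, CHROMS, FlankSpec(2000))
            for cls, regions in (("flank_5p", five),
                                 ("numts_locus",
                                  [(x.chrom, x.start, x.end) for x in xs]),
                                 ("flank_3p", three)):
                brute = 0
                for _, rs, re_, _, _, _ in reps:
                    hit = any(any(rs <= pos < re_ for pos in range(s, e))
                              for _, s, e in regions)
                    # per-base membership scan (slow but independent)
                    hit = any(max(rs, s) < min(re_, e) for _, s, e in regions)
                    brute += hit
                assert table.loc[cls, "count"] == brute


class TestIntervalSubtract:
    def test_hole_in_middle(self):
        assert interval_subtract([(0, 100)], [(40, 60)]) == [(0, 40), (60, 100)]

    def test_disjoint_b_leaves_a(self):
        assert interval_subtract([(0, 50)], [(60, 80)]) == [(0, 50)]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 200), st.integers(1, 60)),
                    min_size=0, max_size=6),
           st.lists(st.tuples(st.integers(0, 200), st.integers(1, 60)),
                    min_size=0, max_size=6))
    def test_matches_per_base_membership(self, a_raw, b_raw):
        a = [(s, s + l) for s, l in a_raw]
        b = [(s, s + l) for s, l in b_raw]
        got = interval_subtract(a, b)
        in_a = set()
        for s, e in a:
            in_a.update(range(s, e))
        in_b = set()
        for s, e in b:
            in_b.update(range(s, e))
        expect = in_a - in_b
        got_set = set()
        for s, e in got:
            assert s < e
            got_set.update(range(s, e))
        assert got_set == expect
        # result is maximal disjoint sorted intervals
        for (s1, e1), (s2, e2) in zip(got, got[1:]):
            assert e1 < s2


class TestReFreeSubset:
    def test_no_repeats_keeps_all(self):
        xs = [mk_numts(), mk_numts(start=50_000, end=51_000)]
        assert re_free_subset(xs, [], CHROMS) == xs

    def test_repeat_in_flank_excludes(self):
        xs = [mk_numts(), mk_numts(start=50_000, end=51_000)]
        reps = [("chr1", 4500, 4600, "SINE", 0, "+")]   # in 1-kb flank of 1st
        assert re_free_subset(xs, reps, CHROMS) == xs[1:]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(8)
        xs = [mk_numts(start=int(s), end=int(s) + 500)
              for s in rng.integers(3000, 90_000, 6)]
        reps = []
        for i in range(12):
            s = int(rng.integers(0, 99_000))
            reps.append(("chr1", s, s + 200, f"r{i}", 0, "+"))
        got = {x.id for x in re_free_subset(xs, reps, CHROMS)}
        brute = set()
        for x in xs:
            window = (x.start - 1000, x.end + 1000)
            if not any(max(rs, window[0]) < min(re_, window[1])
                       for _, rs, re_, _, _, _ in reps):
                brute.add(x.id)
        assert got == brute


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [10, 20, 25, 90]})
        rep = spearman_matrix(df)
        assert rep.rho[("x", "y")] == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        df = pd.DataFrame({"x": [1.0, 2.5, 3.0], "y": [-1.0, -2.5, -3.0]})
        rep = spearman_matrix(df)
        assert rep.rho[("x", "y")] == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        x = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3]
        y = [2, 7, 1, 8, 2, 8, 1, 8, 2, 8]
        df = pd.DataFrame({"x": x, "y": y})
        rep = spearman_matrix(df)
        assert rep.rho[("x", "y")] == pytest.approx(spearman_oracle(x, y))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        r1 = spearman_matrix(pd.DataFrame({"x": x, "y": y})).rho[("x", "y")]
        r2 = spearman_matrix(pd.DataFrame({"x": np.exp(3 * x),
                                           "y": y ** 3})).rho[("x", "y")]
        assert r1 == pytest.approx(r2)

    def test_constant_variable_reported_missing(self):
        df = pd.DataFrame({"x": [1, 1, 1, 1], "y": [1, 2, 3, 4],
                           "z": [4, 3, 2, 1]})
        rep = spearman_matrix(df)
        assert np.isnan(rep.rho[("x", "y")])
        assert rep.rho[("y", "z")] == pytest.approx(-1.0)

    def test_bonferroni_adjustment(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 1, 4, 3],
                           "c": [4, 4, 1, 2]})
        rep = spearman_matrix(df, alpha=0.06)
        assert rep.alpha_adj == pytest.approx(0.06 / 3)
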