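"""Pair joining, noise classification, duplicate removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlohic.fragments import RestrictionSite, digest_genome
from dlohic.mapping import TagAlignment
from dlohic.pairs import (PairClassParams, PairRecord, _sort_key, classify_pair,
                          deduplicate, join_pairs, summarize_pairs)


def _aln(read_id, chrom="chr1", pos=100, strand="+", category="unique",
         side="left", length=20):
    return TagAlignment(read_id, side, chrom, pos, pos + length, strand,
                        37, category)


def _pair(read_id, pos_l, pos_r, strand_l="+", strand_r="+", chrom_l="chr1",
          chrom_r="chr2", linker="AA"):
    return PairRecord(read_id,
                      _aln(read_id, chrom_l, pos_l, strand_l),
                      _aln(read_id, chrom_r, pos_r, strand_r, side="right"),
                      linker_type=linker, cls="valid")


class TestJoin:
    def test_intersection_and_singletons(self):
        left = [_aln("r1"), _aln("r2")]
        right = [_aln("r2", side="right"), _aln("r3", side="right")]
        pairs, singletons = join_pairs(left, right)
        assert [p.read_id for p in pairs] == ["r2"]
        assert singletons == 2

    def test_disjoint_sides_give_no_pairs(self):
        pairs, singletons = join_pairs([_aln("a")], [_aln("b", side="right")])
        assert pairs == [] and singletons == 2

    def test_duplicate_read_id_rejected(self):
        with pytest.raises(ValueError):
            join_pairs([_aln("r1"), _aln("r1")], [])

    def test_non_unique_alignment_rejected(self):
        with pytest.raises(ValueError):
            join_pairs([_aln("r1", category="multi")], [])


class TestClassify:
    @pytest.fixture(scope="class")
    def index(self):
        rng = np.random.default_rng(29)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60_000))
        return digest_genome({"chr1": seq, "chr2": seq[::-1]},
                             RestrictionSite.from_string("T^TAA"))

    def test_same_fragment_is_self_ligation(self, index):
        start, end = index.bounds("chr1", 17)
        p = _pair("p", start, end - 21, chrom_r="chr1")
        out = classify_pair(p, index)
        assert out.cls == "self_ligation" and out.frag_l == out.frag_r == 17

    def test_adjacent_fragments_are_re_ligation(self, index):
        s17, e17 = index.bounds("chr1", 17)
        s18, _ = index.bounds("chr1", 18)
        out = classify_pair(_pair("p", s17, s18, chrom_r="chr1"), index)
        assert out.cls == "re_ligation"
        assert abs(out.frag_l - out.frag_r) == 1

    def test_short_range_boundary_inclusive(self, index):
        params = PairClassParams()
        out = classify_pair(_pair("p", 1000, 5999, chrom_r="chr1"), index, params)
        if out.cls == "valid":
            assert out.range == "short"  # 4999 <= 5000
        out2 = classify_pair(_pair("p", 1000, 6001, chrom_r="chr1"), index, params)
        assert abs(out2.pos5_l - out2.pos5_r) == 5001
        if out2.cls == "valid":
            assert out2.range == "long"

    def test_heterodimer_takes_precedence(self, index):
        start, end = index.bounds("chr1", 5)
        p = _pair("p", start, end - 21, chrom_r="chr1", linker="AB")
        assert classify_pair(p, index).cls == "heterodimer"

    def test_inter_chromosomal_is_valid_with_na_range(self, index):
        out = classify_pair(_pair("p", 500, 700), index)
        assert out.cls == "valid" and out.locality == "inter" and out.range == "n/a"


class TestDeduplicate:
    def test_within_window_flagged(self):
        pairs = sorted([_pair("a", 100, 500, "+", "-"),
                        _pair("b", 101, 502, "+", "-")], key=_sort_key)
        out = deduplicate(pairs)
        assert [p.duplicate for p in out] == [False, True]

    def test_strand_mismatch_not_duplicate(self):
        pairs = sorted([_pair("a", 100, 500, "+", "-"),
                        _pair("b", 100, 500, "-", "-")], key=_sort_key)
        assert not any(p.duplicate for p in deduplicate(pairs))

    def test_outside_window_not_duplicate(self):
        pairs = sorted([_pair("a", 100, 500), _pair("b", 103, 500)], key=_sort_key)
        assert not any(p.duplicate for p in deduplicate(pairs))

    def test_chain_collapses_by_single_linkage(self):
        pairs = sorted([_pair("a", 100, 500), _pair("b", 102, 500),
                        _pair("c", 104, 500)], key=_sort_key)
        out = deduplicate(pairs)
        assert [p.duplicate for p in out] == [False, True, True]

    def test_idempotent(self):
        rng = np.random.default_rng(33)
        pairs = sorted((_pair(f"r{i}", int(rng.integers(0, 300)),
                              int(rng.integers(0, 300)),
                              "+-"[rng.integers(2)], "+-"[rng.integers(2)])
                        for i in range(60)), key=_sort_key)
        once = deduplicate(pairs)
        twice = deduplicate(once)
        assert [p.duplicate for p in once] == [p.duplicate for p in twice]

    def test_unsorted_input_rejected(self):
        pairs = [_pair("a", 200, 500), _pair("b", 100, 500)]
        with pytest.raises(ValueError):
            deduplicate(pairs)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 60), st.integers(0, 60),
                              st.booleans()), min_size=1, max_size=25))
    def test_retained_set_depends_only_on_sorted_order(self, spec):
        pairs = [
            _pair(f"r{i}", a, b, "+" if s else "-")
            for i, (a, b, s) in enumerate(spec)
        ]
        ordered = sorted(pairs, key=_sort_key)
        out1 = deduplicate(ordered)
        # a different construction order of the same multiset
        out2 = deduplicate(sorted(list(reversed(pairs)), key=_sort_key))
        assert {p.read_id for p in out1 if not p.duplicate} == \
               {p.read_id for p in out2 if not p.duplicate}
        # exactly one retained pair per cluster and flags partition the input
        assert len(out1) == len(pairs)


def test_summary_reconciles_counts():
    pairs = [_pair("a", 100, 500), _pair("b", 200, 600, linker="AB")]
    pairs[1].cls = "heterodimer"
    summary = summarize_pairs(pairs, singletons=3)
    assert summary["pairs"] == 2 and summary["singletons"] == 3
    assert sum(summary["classes"].values()) == 2
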