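"""Binning, O/E normalization, similarity measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlohic.mapping import TagAlignment
from dlohic.matrix import (ContactMatrix, MatrixSpec, bin_pairs, coarsen,
                           cosine_similarity, genome_vector, matrix_to_vector,
                           oe_normalize, pearson_correlation)
from dlohic.pairs import PairRecord

SIZES = {"chr1": 10_000, "chr2": 6_000}


def _pair(read_id, chrom1, pos1, chrom2, pos2, linker="AA", cls="valid",
          duplicate=False):
    tl = TagAlignment(read_id, "left", chrom1, pos1, pos1 + 20, "+", 37, "unique")
    tr = TagAlignment(read_id, "right", chrom2, pos2, pos2 + 20, "+", 37, "unique")
    return PairRecord(read_id, tl, tr, 0, 5, linker, cls, duplicate)


class TestBinning:
    def test_intra_pair_in_upper_triangle_cell(self):
        spec = MatrixSpec(1000, SIZES)
        mats = bin_pairs([_pair("a", "chr1", 150, "chr1", 950)], spec)
        assert mats[("chr1", "chr1")].counts == {(0, 0): 1.0}

    def test_inter_pair_canonical_chrom_order(self):
        spec = MatrixSpec(1000, SIZES)
        mats = bin_pairs([_pair("a", "chr2", 500, "chr1", 2500)], spec)
        assert mats[("chr1", "chr2")].counts == {(2, 0): 1.0}

    def test_count_conservation(self):
        rng = np.random.default_rng(44)
        pairs = [_pair(f"r{i}", "chr1", int(rng.integers(0, 9000)),
                       "chr1", int(rng.integers(0, 9000)))
                 for i in range(500)]
        for res in (500, 1000, 2500):
            mats = bin_pairs(pairs, MatrixSpec(res, SIZES))
            assert sum(m.total for m in mats.values()) == 500

    def test_excludes_noise_duplicates_heterodimers(self):
        pairs = [
            _pair("ok", "chr1", 10, "chr1", 5000),
            _pair("dup", "chr1", 10, "chr1", 5000, duplicate=True),
            _pair("self", "chr1", 10, "chr1", 40, cls="self_ligation"),
            _pair("het", "chr1", 10, "chr1", 5000, linker="AB", cls="heterodimer"),
        ]
        mats = bin_pairs(pairs, MatrixSpec(1000, SIZES))
        assert sum(m.total for m in mats.values()) == 1

    def test_position_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError):
            bin_pairs([_pair("a", "chr2", 6_500, "chr1", 10)],
                      MatrixSpec(1000, SIZES))

    def test_coarsening_equals_direct_binning(self):
        rng = np.random.default_rng(45)
        pairs = [_pair(f"r{i}", "chr1", int(rng.integers(0, 9999)),
                       "chr1", int(rng.integers(0, 9999)))
                 for i in range(300)]
        fine = bin_pairs(pairs, MatrixSpec(500, SIZES))[("chr1", "chr1")]
        direct = bin_pairs(pairs, MatrixSpec(2000, SIZES))[("chr1", "chr1")]
        assert coarsen(fine, 4).counts == direct.counts


class TestOE:
    def test_constant_matrix_becomes_ones(self):
        spec = MatrixSpec(1000, SIZES)
        m = ContactMatrix("chr1", "chr1", spec)
        n = spec.n_bins("chr1")
        for i in range(n):
            for j in range(i, n):
                m.counts[(i, j)] = 7.0
        oe = oe_normalize(m)
        assert all(abs(v - 1.0) < 1e-12 for v in oe.counts.values())

    def test_hand_computed_three_by_three(self):
        spec = MatrixSpec(2000, {"c": 6000})
        m = ContactMatrix("c", "c", spec)
        m.counts = {(0, 0): 4.0, (1, 1): 4.0, (2, 2): 4.0, (0, 1): 2.0, (1, 2): 2.0}
        oe = oe_normalize(m)
        # expected per diagonal: d0 = 4, d1 = 2, d2 = 0
        assert oe.counts == {(0, 0): 1.0, (1, 1): 1.0, (2, 2): 1.0,
                             (0, 1): 1.0, (1, 2): 1.0}

    def test_empty_diagonal_maps_to_zero(self):
        spec = MatrixSpec(2000, {"c": 6000})
        m = ContactMatrix("c", "c", spec)
        m.counts = {(0, 2): 0.0, (0, 0): 3.0}
        oe = oe_normalize(m)
        assert oe.counts[(0, 2)] == 0.0

    def test_diagonal_means_are_one(self):
        rng = np.random.default_rng(46)
        spec = MatrixSpec(250, {"c": 10_000})
        m = ContactMatrix("c", "c", spec)
        n = spec.n_bins("c")
        for _ in range(800):
            i, j = sorted(rng.integers(0, n, 2))
            m.add(int(i), int(j))
        dense = oe_normalize(m).dense(symmetrize=False)
        for d in range(n):
            diag = np.diagonal(dense, offset=d)
            if diag.sum() > 0:
                assert abs(diag.mean() - 1.0) < 1e-9

    def test_inter_matrix_rejected(self):
        m = ContactMatrix("chr1", "chr2", MatrixSpec(1000, SIZES))
        with pytest.raises(ValueError):
            oe_normalize(m)


class TestVectorsAndSimilarity:
    def test_row_major_flattening(self):
        m = ContactMatrix("chr1", "chr2", MatrixSpec(5000, SIZES))
        m.counts = {(0, 0): 1.0, (0, 1): 2.0, (1, 0): 3.0, (1, 1): 4.0}
        assert list(matrix_to_vector(m)) == [1.0, 2.0, 3.0, 4.0]

    def test_symmetric_expansion_of_upper_triangle(self):
        m = ContactMatrix("c", "c", MatrixSpec(3000, {"c": 6000}))
        m.counts = {(0, 0): 1.0, (0, 1): 2.0, (1, 1): 4.0}
        assert list(matrix_to_vector(m)) == [1.0, 2.0, 2.0, 4.0]

    def test_vector_length_is_nbins_squared(self):
        m = ContactMatrix("c", "c", MatrixSpec(1000, {"c": 5000}))
        assert matrix_to_vector(m).size == 25

    def test_identity_and_orthogonality(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert pearson_correlation(a, a) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_matches_scipy_pearson(self):
        from scipy import stats
        rng = np.random.default_rng(47)
        a, b = rng.random(50), rng.random(50)
        assert pearson_correlation(a, b) == pytest.approx(stats.pearsonr(a, b)[0])

    def test_undefined_cases_raise(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])
        with pytest.raises(ValueError):
            pearson_correlation([2, 2], [1, 3])
        with pytest.raises(ValueError):
            cosine_similarity([1, 2], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=30),
           st.permutations(range(30)))
    def test_similarity_invariant_under_joint_permutation(self, values, perm):
        a = np.asarray(values, dtype=float)
        if np.linalg.norm(a) == 0 or np.var(a) == 0:
            return
        b = a * 1.7 + 0.3
        idx = np.asarray([p for p in perm if p < len(a)])
        assert cosine_similarity(a[idx], b[idx]) == pytest.approx(
            cosine_similarity(a, b))
        assert pearson_correlation(a[idx], b[idx]) == pytest.approx(
            pearson_correlation(a, b))


def test_genome_vector_lexicographic_concatenation():
    spec = MatrixSpec(5000, SIZES)
    m1 = ContactMatrix("chr1", "chr1", spec)
    m2 = ContactMatrix("chr1", "chr2", spec)
    m1.counts = {(0, 0): 1.0}
    m2.counts = {(0, 1): 2.0}
    v = genome_vector({("chr1", "chr2"): m2, ("chr1", "chr1"): m1})
    assert v.size == 4 + 4 and v[0] == 1.0 and list(v[4:]) == [0.0, 2.0, 0.0, 0.0]
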