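"""Linker enumeration/alignment, adapter handling, splitting, discovery."""

import numpy as np
import pytest

from dlohic._seq import FastqRecord, revcomp
from dlohic.preprocess import (AdapterParams, DetectionError, LinkerAlignParams,
                               align_linker, align_linker_batch,
                               detect_adapter_consensus, discover_linker_and_site,
                               enumerate_full_linkers, split_by_linker,
                               trim_adapter, trim_adapter_batch)
from dlohic.simulate import SimParams, simulate_genome, simulate_reads


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestEnumerateFullLinkers:
    def test_two_half_linkers_give_four_types(self, hindiii_design):
        ls = enumerate_full_linkers(hindiii_design["half_linkers"])
        assert ls.type_labels == ["AA", "AB", "BA", "BB"]
        assert ls.protocol == "DLO"

    def test_one_half_linker_gives_aa_only(self, msei_design):
        ls = enumerate_full_linkers(msei_design["half_linkers"])
        assert ls.type_labels == ["AA"]
        assert ls.protocol == "in-situ-DLO"

    def test_full_linker_length_is_sum_of_halves(self, hindiii_design):
        ls = enumerate_full_linkers(hindiii_design["half_linkers"])
        assert all(len(f.sequence) == 40 for f in ls.full_linkers)

    def test_head_to_head_assembly(self):
        ls = enumerate_full_linkers(["ACGTAC", "GGATCA"])
        by = {(f.type_label, f.variant): f.sequence for f in ls.full_linkers}
        assert by[("AB", "rc")] == "ACGTAC" + revcomp("GGATCA")
        assert by[("AB", "cat")] == "ACGTACGGATCA"

    def test_three_half_linkers_rejected(self):
        with pytest.raises(ValueError):
            enumerate_full_linkers(["ACGT", "AGGT", "ATTT"])


class TestAlignLinker:
    def test_planted_linker_found_with_exact_coordinates(self, hindiii_design):
        ls = enumerate_full_linkers(hindiii_design["half_linkers"])
        rng = np.random.default_rng(0)
        full_ba = next(f.sequence for f in ls.full_linkers
                       if f.type_label == "BA" and f.variant == "rc")
        read = _rand(rng, 22) + full_ba + _rand(rng, 18)
        hit = align_linker(read, ls)
        assert hit is not None
        assert (hit.linker_type, hit.linker_start, hit.linker_end) == ("BA", 22, 62)
        assert hit.align_score == 40
        assert hit.left_tag == read[:22] and hit.right_tag == read[62:]

    def test_reverse_orientation_recorded(self, msei_design):
        ls = enumerate_full_linkers(msei_design["half_linkers"])
        rng = np.random.default_rng(1)
        full = next(f.sequence for f in ls.full_linkers if f.variant == "cat")
        read = _rand(rng, 20) + revcomp(full) + _rand(rng, 20)
        hit = align_linker(read, ls)
        assert hit is not None and hit.orientation == "reverse"

    def test_random_read_scores_below_threshold(self, msei_design):
        ls = enumerate_full_linkers(msei_design["half_linkers"])
        rng = np.random.default_rng(123)
        assert align_linker(_rand(rng, 60), ls) is None

    def test_empty_linker_set_rejected(self):
        from dlohic.preprocess import LinkerSet
        with pytest.raises(ValueError):
            align_linker_batch([FastqRecord("r", "ACGT" * 20, "I" * 80)],
                               LinkerSet({}, []))

    def test_self_consistency_reconstructs_read(self, hindiii_library, hindiii_params):
        _genome, reads, _truth = hindiii_library
        ls = enumerate_full_linkers(hindiii_params.half_linkers)
        trimmed, starts = trim_adapter_batch(reads[:300], hindiii_params.adapter)
        hits = align_linker_batch(trimmed, ls, adapter_starts=starts)
        seen = 0
        for rec, hit in zip(trimmed, hits):
            if hit is None:
                continue
            seen += 1
            linker = rec.seq[hit.linker_start : hit.linker_end]
            upto = hit.adapter_start if hit.adapter_start is not None else len(rec.seq)
            assert hit.left_tag + linker + hit.right_tag == rec.seq[:upto]
        assert seen > 100


class TestAdapter:
    def test_consensus_recovers_planted_adapter(self, hindiii_library, hindiii_params):
        _genome, reads, truth = hindiii_library
        ls = enumerate_full_linkers(hindiii_params.half_linkers)
        with_linker = [r for r in reads
                       if not r.read_id.startswith("no_linker")][:100]
        assert detect_adapter_consensus(with_linker, ls) == hindiii_params.adapter

    def test_identical_reads_conserve_the_full_tail(self, hindiii_params):
        """With copies of one read, every post-linker base has frequency
        1.0, so the consensus is the whole conserved tail; it must end in
        the planted adapter."""
        ls = enumerate_full_linkers(hindiii_params.half_linkers)
        full = ls.full_linkers[0].sequence
        rng = np.random.default_rng(4)
        construct = _rand(rng, 20) + full + _rand(rng, 20) + hindiii_params.adapter
        reads = [FastqRecord(f"r{i}", construct, "I" * len(construct))
                 for i in range(100)]
        consensus = detect_adapter_consensus(reads, ls)
        assert consensus is not None and consensus.endswith(hindiii_params.adapter)

    def test_random_tails_give_no_consensus(self, hindiii_params):
        ls = enumerate_full_linkers(hindiii_params.half_linkers)
        full = ls.full_linkers[0].sequence
        rng = np.random.default_rng(5)
        reads = []
        for i in range(100):
            seq = _rand(rng, 20) + full + _rand(rng, 60)
            reads.append(FastqRecord(f"r{i}", seq, "I" * len(seq)))
        assert detect_adapter_consensus(reads, ls) is None

    def test_empty_input_rejected(self, hindiii_params):
        ls = enumerate_full_linkers(hindiii_params.half_linkers)
        with pytest.raises(ValueError):
            detect_adapter_consensus([], ls)

    def test_trim_at_construct_end(self):
        rng = np.random.default_rng(6)
        adapter = _rand(rng, 70)
        construct = _rand(rng, 80)
        read = FastqRecord("r", (construct + adapter)[:150], "I" * 150)
        trimmed, start = trim_adapter(read, adapter)
        assert start == 80 and trimmed.seq == construct

    def test_empty_adapter_is_identity(self):
        read = FastqRecord("r", "ACGT" * 10, "I" * 40)
        assert trim_adapter(read, "") == (read, None)

    def test_one_mismatch_in_twenty_still_trimmed(self):
        rng = np.random.default_rng(7)
        adapter = _rand(rng, 20)
        construct = _rand(rng, 60)
        noisy = "T" + adapter[1:] if adapter[0] != "T" else "A" + adapter[1:]
        read = FastqRecord("r", construct + noisy, "I" * 80)
        _trimmed, start = trim_adapter(read, adapter)
        assert start == 60

    def test_batch_agrees_with_scalar_on_simulated_reads(self, hindiii_library,
                                                         hindiii_params):
        _genome, reads, _truth = hindiii_library
        sample = reads[:200]
        batch, starts = trim_adapter_batch(sample, hindiii_params.adapter)
        for rec, brec, s in zip(sample, batch, starts):
            srec, ss = trim_adapter(rec, hindiii_params.adapter)
            assert (srec.seq, ss) == (brec.seq, s)


class TestSplit:
    def test_category_counts_sum_to_input(self, hindiii_library, hindiii_params,
                                          tmp_path):
        _genome, reads, truth = hindiii_library
        ls = enumerate_full_linkers(hindiii_params.half_linkers)
        trimmed, starts = trim_adapter_batch(reads, hindiii_params.adapter)
        hits = align_linker_batch(trimmed, ls, adapter_starts=starts)
        res = split_by_linker(zip(trimmed, hits), tmp_path, compress=False)
        counts = res["counts"]
        assert counts["total"] == len(reads)
        assert sum(v for k, v in counts.items() if k != "total") == counts["total"]
        assert len(res["files"]) == 4  # AA, AB, BA, BB
        assert (tmp_path / "linker_hits.tsv").exists()

    def test_planted_linker_sensitivity(self, hindiii_library, hindiii_params):
        """>= 99.9% of error-free reads get exact linker type + coordinates."""
        _genome, reads, truth = hindiii_library
        ls = enumerate_full_linkers(hindiii_params.half_linkers)
        trimmed, starts = trim_adapter_batch(reads, hindiii_params.adapter)
        hits = align_linker_batch(trimmed, ls, adapter_starts=starts)
        by_id = truth.set_index("read_id")
        good = total = 0
        tl = hindiii_params.tag_len
        for rec, hit in zip(trimmed, hits):
            row = by_id.loc[rec.read_id]
            if row["class"] == "no_linker":
                continue
            total += 1
            if (hit is not None and hit.linker_type == row["linker_type"]
                    and hit.linker_start == tl and hit.linker_end == tl + 40):
                good += 1
        assert total > 0 and good / total >= 0.999

    def test_no_hits_conserves_counts(self, tmp_path):
        rng = np.random.default_rng(8)
        reads = [FastqRecord(f"r{i}", _rand(rng, 150), "I" * 150) for i in range(20)]
        res = split_by_linker(((r, None) for r in reads), tmp_path)
        assert res["counts"]["no_linker"] == 20 and res["counts"]["total"] == 20


class TestDiscovery:
    @pytest.mark.parametrize("design", ["msei", "hindiii"])
    def test_recovers_planted_design_exactly(self, design, msei_design,
                                             hindiii_design):
        cfg = {"msei": msei_design, "hindiii": hindiii_design}[design]
        params = SimParams(seed=3, counts={"valid": 12000, "self_ligation": 100,
                                           "re_ligation": 100, "heterodimer": 600,
                                           "no_linker": 600}, **cfg)
        reads, _truth = simulate_reads(params)
        halves, site = discover_linker_and_site(reads, sample_size=8000)
        assert site == params.site
        assert list(halves) == list(params.half_linkers)

    def test_uniform_random_reads_fail(self):
        rng = np.random.default_rng(0)
        junk = [_rand(rng, 150) for _ in range(1500)]
        with pytest.raises(DetectionError):
            discover_linker_and_site(junk, sample_size=1500)


def test_align_params_validation():
    with pytest.raises(ValueError):
        LinkerAlignParams(match_score=0)
    with pytest.raises(ValueError):
        LinkerAlignParams(mismatch_score=1)
    with pytest.raises(ValueError):
        LinkerAlignParams(min_score_fraction=0.0)
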