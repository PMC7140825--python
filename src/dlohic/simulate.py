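"""Synthetic DLO Hi-C libraries with per-read ground truth.

The simulator emulates the sequenced construct — a ~20-bp genomic tag, the
~40-bp full linker, a second tag, then sequencing adapter — on a random
genome carrying a configurable restriction site.  Tags end exactly at cut
sites, as real digestion dictates: a left tag read on the plus strand ends
at the top-strand cut; minus-strand tags end at the bottom-strand cut, so
the conserved cut-site remnant (``site[:cut]`` before the linker,
``site[cut:]`` after) is identical on both strands for the
reverse-complement-palindromic sites this protocol uses.

Every planted construct's truth labels (positions, fragment ordinals,
class, range) are computed with the pipeline's own coordinate definitions
(5'-most mapped base; fragment containing it), so recovery comparisons are
exact.  For 5'-overhang cutters a minus-strand *right* tag's anchor base
falls ``overhang`` bases past the top-strand cut, i.e. into the next
fragment; such tags are only generated when ``allow_minus_right`` is set,
and the default strand mix keeps every label exact.

Constructs are planted at pairwise-distinct (cut site, strand)
combinations per end.  Distinct cut sites are at least the recognition
length apart, which is larger than the 2-bp duplicate window, so the only
pairs flagged as PCR duplicates are the planted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import FastqRecord, revcomp, write_fasta, write_fastq
from .fragments import FragmentIndex, RestrictionSite, assign_fragment, digest_genome

__all__ = ["SimParams", "simulate_genome", "simulate_reads", "simulate_library"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Published library designs (enzyme + half-linkers) usable as presets.
DESIGNS = {
    "hindiii": {
        "site": "A^AGCTT",
        "half_linkers": ("GTCGGAGTTCTTGAGCTAAG", "GTCGGAGTTCTTGAGCTATC"),
    },
    "msei": {
        "site": "T^TAA",
        "half_linkers": ("GTCGGAGAACCAGTAGCT",),
    },
}


@dataclass
class SimParams:
    seed: int = 0
    n_chroms: int = 2
    chrom_size: int = 100_000
    site: str = "A^AGCTT"
    half_linkers: tuple[str, ...] = (
        "GTCGGAGTTCTTGAGCTAAG",
        "GTCGGAGTTCTTGAGCTATC",
    )
    adapter: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
    read_len: int = 150
    tag_len: int = 20
    counts: dict[str, int] = field(default_factory=lambda: {
        "valid": 1000,
        "self_ligation": 100,
        "re_ligation": 100,
        "heterodimer": 100,
        "no_linker": 100,
    })
    duplicate_rate: float = 0.05
    snp_rate: float = 0.0
    inter_fraction: float = 0.2
    short_fraction: float = 0.25
    aa_fraction: float = 0.55
    site_spacing: int = 1_500
    min_frag_len: int = 60
    allow_minus_right: bool = False
    reverse_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("duplicate_rate", "snp_rate", "inter_fraction",
                     "short_fraction", "aa_fraction", "reverse_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("construct counts must be >= 0")
        if self.chrom_size < 20 * self.tag_len or self.chrom_size < 4 * self.site_spacing:
            raise ValueError("genome too small for the requested site density")
        RestrictionSite.from_string(self.site)

    @property
    def restriction_site(self) -> RestrictionSite:
        return RestrictionSite.from_string(self.site)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, n, dtype=np.uint8)]).decode()


def simulate_genome(params: SimParams) -> dict[str, str]:
    """Random genome with the restriction site planted every ~site_spacing bp.

    Natural occurrences of the site add further cuts; the fragment truth is
    whatever in silico digestion of the returned sequence yields.
    """
    rng = np.random.default_rng(params.seed)
    site = params.restriction_site
    genome = {}
    for c in range(params.n_chroms):
        arr = _BASES[rng.integers(0, 4, params.chrom_size, dtype=np.uint8)].copy()
        pos = params.site_spacing // 2
        while pos + len(site.sequence) < params.chrom_size:
            arr[pos : pos + len(site.sequence)] = np.frombuffer(
                site.sequence.encode(), dtype=np.uint8
            )
            pos += params.site_spacing + int(rng.integers(0, params.site_spacing // 2))
        genome[f"chr{c + 1}"] = arr.tobytes().decode()
    return genome


@dataclass
class _Tag:
    """One realized tag: its sequence plus its pipeline-definition truth."""

    seq: str
    chrom: str
    pos: int  # leftmost mapped coordinate
    end: int
    strand: str
    pos5: int
    frag: int


class _Sampler:
    def __init__(self, params: SimParams, genome: dict[str, str],
                 index: FragmentIndex, rng: np.random.Generator):
        self.p = params
        self.genome = genome
        self.index = index
        self.rng = rng
        self.site = params.restriction_site
        tl = params.tag_len
        margin = tl + self.site.overhang + 5
        self.cuts: dict[str, np.ndarray] = {}
        for chrom in genome:
            cand = index.cut_positions(chrom)
            starts = index.starts[chrom]
            size = index.chrom_sizes[chrom]
            ends = np.append(starts[1:], size)
            frag_len = ends - starts
            ok = []
            for c in cand:
                k = int(np.searchsorted(starts, c) - 1)  # upstream fragment ordinal
                if (
                    margin <= c <= size - margin
                    and frag_len[k] >= params.min_frag_len
                    and k + 1 < len(starts)
                    and frag_len[k + 1] >= params.min_frag_len
                ):
                    ok.append(int(c))
            self.cuts[chrom] = np.asarray(ok, dtype=np.int64)
            if len(ok) < 10:
                raise ValueError(f"too few usable cut sites on {chrom}")
        self.used: set[tuple] = set()
        # systematic pools for classes that consume one locus each
        self._self_pool: list[tuple[str, int, int]] = []
        self._re_pool: list[tuple[str, int]] = []
        for chrom in genome:
            cuts = self.cuts[chrom]
            starts = index.starts[chrom]
            for i in range(len(cuts) - 1):
                q, p_cut = int(cuts[i]), int(cuts[i + 1])
                # one fragment iff no further cut lies strictly between
                lo = np.searchsorted(starts, q, side="right")
                hi = np.searchsorted(starts, p_cut, side="left")
                if lo == hi:
                    self._self_pool.append((chrom, q, p_cut))
            self._re_pool.extend((chrom, int(c)) for c in cuts)
        rng.shuffle(self._self_pool)
        rng.shuffle(self._re_pool)

    def tag(self, chrom: str, cut: int, side: str, strand: str,
            jitter: int = 0) -> _Tag:
        """Extract a tag abutting ``cut`` (optionally shifted by jitter)."""
        g = self.genome[chrom]
        tl = self.p.tag_len
        ovh = self.site.overhang
        if side == "left":
            if strand == "+":
                pos, end = cut - tl + jitter, cut + jitter
                seq = g[pos:end]
            else:
                pos, end = cut + ovh + jitter, cut + ovh + tl + jitter
                seq = revcomp(g[pos:end])
        else:
            if strand == "+":
                pos, end = cut + jitter, cut + tl + jitter
                seq = g[pos:end]
            else:
                pos, end = cut + ovh - tl + jitter, cut + ovh + jitter
                seq = revcomp(g[pos:end])
        pos5 = pos if strand == "+" else end - 1
        frag = assign_fragment(self.index, chrom, pos5)
        return _Tag(seq, chrom, pos, end, strand, pos5, frag)

    def _left_strand(self) -> str:
        return "+" if self.rng.random() < 0.5 else "-"

    def _right_strand(self) -> str:
        if self.p.allow_minus_right:
            return "+" if self.rng.random() < 0.5 else "-"
        return "+"

    def _register(self, left: _Tag, right: _Tag) -> bool:
        key = (left.chrom, left.pos5, left.strand,
               right.chrom, right.pos5, right.strand)
        if key in self.used:
            return False
        self.used.add(key)
        return True

    def valid_pair(self) -> tuple[_Tag, _Tag]:
        p, rng = self.p, self.rng
        for _ in range(200):
            inter = rng.random() < p.inter_fraction and len(self.genome) > 1
            chrom_l = str(rng.choice(list(self.genome)))
            cuts_l = self.cuts[chrom_l]
            i = int(rng.integers(len(cuts_l)))
            cut_l = int(cuts_l[i])
            if inter:
                others = [c for c in self.genome if c != chrom_l]
                chrom_r = others[int(rng.integers(len(others)))]
                cuts_r = self.cuts[chrom_r]
                cut_r = int(cuts_r[int(rng.integers(len(cuts_r)))])
            else:
                chrom_r = chrom_l
                short = rng.random() < p.short_fraction
                lo, hi = (300, 4_500) if short else (6_000, p.chrom_size)
                a = np.searchsorted(cuts_l, [cut_l - hi, cut_l - lo, cut_l + lo, cut_l + hi])
                cand = np.concatenate([cuts_l[a[0]:a[1]], cuts_l[a[2]:a[3]]])
                # keep >=3 cut indices apart so fragment ordinals differ by >=2
                cand = cand[np.abs(np.searchsorted(cuts_l, cand) - i) >= 3]
                if len(cand) == 0:
                    continue
                cut_r = int(cand[int(rng.integers(len(cand)))])
            left = self.tag(chrom_l, cut_l, "left", self._left_strand())
            right = self.tag(chrom_r, cut_r, "right", self._right_strand())
            if left.chrom == right.chrom and abs(left.frag - right.frag) <= 1:
                continue
            if self._register(left, right):
                return left, right
        raise RuntimeError("could not place a valid pair; genome too small?")

    def self_ligation(self) -> tuple[_Tag, _Tag]:
        # both ends of one fragment [q, p_cut) around one linker
        while self._self_pool:
            chrom, q, p_cut = self._self_pool.pop()
            left = self.tag(chrom, p_cut, "left", "+")
            right = self.tag(chrom, q, "right", "+")
            if left.frag == right.frag and self._register(left, right):
                return left, right
        raise ValueError(
            "more self-ligation constructs requested than qualifying fragments"
        )

    def re_ligation(self) -> tuple[_Tag, _Tag]:
        # two adjacent fragments re-joined at their shared cut
        while self._re_pool:
            chrom, cut = self._re_pool.pop()
            left = self.tag(chrom, cut, "left", "+")
            right = self.tag(chrom, cut, "right", "+")
            if abs(left.frag - right.frag) == 1 and self._register(left, right):
                return left, right
        raise ValueError(
            "more re-ligation constructs requested than qualifying cut sites"
        )


def _full_linker(halves: tuple[str, ...], label: str) -> str:
    h = {"A": halves[0], "B": halves[-1]}
    return h[label[0]] + revcomp(h[label[1]])


def simulate_reads(
    params: SimParams, genome: dict[str, str] | None = None
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Generate labeled reads; returns (records, truth table).

    The truth table has one row per read: class, linker type, per-end
    chromosome / 5' position / strand / fragment ordinal, planted SNP
    counts, and ``duplicate_of`` (empty for originals).
    """
    if genome is None:
        genome = simulate_genome(params)
    index = digest_genome(genome, params.restriction_site)
    rng = np.random.default_rng(params.seed + 1)
    sampler = _Sampler(params, genome, index, rng)
    halves = params.half_linkers
    single = len(halves) == 1

    reads: list[FastqRecord] = []
    rows: list[dict] = []

    def homodimer_label() -> str:
        if single:
            return "AA"
        return "AA" if rng.random() < params.aa_fraction else "BB"

    def mutate(seq: str) -> tuple[str, int]:
        if params.snp_rate <= 0 or rng.random() >= params.snp_rate:
            return seq, 0
        i = int(rng.integers(3, len(seq) - 3))
        alt = "ACGT".replace(seq[i], "")[int(rng.integers(3))]
        return seq[:i] + alt + seq[i + 1 :], 1

    def emit(read_id: str, cls: str, linker_type: str, left: _Tag, right: _Tag,
             duplicate_of: str = "") -> None:
        linker = _full_linker(halves, linker_type)
        lseq, snp_l = mutate(left.seq)
        rseq, snp_r = mutate(right.seq)
        seq = lseq + linker + rseq + params.adapter
        if len(seq) < params.read_len:
            seq += _random_seq(rng, params.read_len - len(seq))
        seq = seq[: params.read_len]
        orientation = "forward"
        if params.reverse_fraction > 0 and rng.random() < params.reverse_fraction:
            seq = revcomp(seq)
            orientation = "reverse"
        reads.append(FastqRecord(read_id, seq, "I" * len(seq)))
        intra = left.chrom == right.chrom
        dist = abs(left.pos5 - right.pos5) if intra else -1
        rows.append({
            "read_id": read_id, "class": cls, "linker_type": linker_type,
            "chrom_l": left.chrom, "pos5_l": left.pos5, "strand_l": left.strand,
            "frag_l": left.frag, "chrom_r": right.chrom, "pos5_r": right.pos5,
            "strand_r": right.strand, "frag_r": right.frag,
            "locality": "intra" if intra else "inter",
            "distance": dist, "snp_l": snp_l, "snp_r": snp_r,
            "orientation": orientation, "duplicate_of": duplicate_of,
        })

    for cls in ("valid", "self_ligation", "re_ligation", "heterodimer"):
        if cls == "heterodimer" and single:
            continue  # heterodimers need two half-linkers
        for k in range(params.counts.get(cls, 0)):
            if cls == "valid":
                left, right = sampler.valid_pair()
                label = homodimer_label()
            elif cls == "self_ligation":
                left, right = sampler.self_ligation()
                label = homodimer_label()
            elif cls == "re_ligation":
                left, right = sampler.re_ligation()
                label = homodimer_label()
            else:
                left, right = sampler.valid_pair()
                label = "AB" if rng.random() < 0.5 else "BA"
            rid = f"{cls}_{k}"
            emit(rid, cls, label, left, right)
            if cls == "valid" and rng.random() < params.duplicate_rate:
                # PCR duplicate: same construct, <=2 bp mapping jitter per end
                jl = int(rng.integers(0, 3))
                jr = int(rng.integers(0, 3))
                cut_l = left.pos + params.tag_len if left.strand == "+" else \
                    left.pos - params.restriction_site.overhang
                cut_r = right.pos if right.strand == "+" else \
                    right.end - params.restriction_site.overhang
                dl = sampler.tag(left.chrom, cut_l, "left", left.strand, jitter=jl)
                dr = sampler.tag(right.chrom, cut_r, "right", right.strand, jitter=jr)
                emit(f"{rid}_dup", cls, label, dl, dr, duplicate_of=rid)

    for k in range(params.counts.get("no_linker", 0)):
        reads.append(FastqRecord(f"no_linker_{k}",
                                 _random_seq(rng, params.read_len),
                                 "I" * params.read_len))
        rows.append({
            "read_id": f"no_linker_{k}", "class": "no_linker", "linker_type": "",
            "chrom_l": "", "pos5_l": -1, "strand_l": "", "frag_l": -1,
            "chrom_r": "", "pos5_r": -1, "strand_r": "", "frag_r": -1,
            "locality": "", "distance": -1, "snp_l": 0, "snp_r": 0,
            "orientation": "", "duplicate_of": "",
        })

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame([rows[i] for i in order])
    return reads, truth


def simulate_library(params: SimParams, out_dir: str | Path) -> dict[str, Path]:
    """Write genome.fa, reads.fq.gz and truth.tsv; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(params)
    reads, truth = simulate_reads(params, genome)
    paths = {
        "genome": out_dir / "genome.fa",
        "reads": out_dir / "reads.fq.gz",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(paths["genome"], genome)
    write_fastq(paths["reads"], reads)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
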