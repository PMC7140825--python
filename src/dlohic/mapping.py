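"""Tag mapping: pluggable aligner backends, chunked and iterative mapping.

Tags (the ~20-bp genomic sequences flanking the linker) are mapped
independently to the reference.  An aligner backend is any object with

    align(reads, max_edit_distance) -> list[RawHit]

returning exactly one hit record per input read.  Two backends ship:

* :class:`MismatchScanAligner` — an exhaustive ≤n-mismatch scan of the
  genome (both strands, no gaps).  Exact and self-contained; intended for
  synthetic genomes up to a few hundred kilobases.
* :class:`BwaAligner` — shells out to ``bwa aln``/``samse`` (or ``bwa mem``
  for long reads) and parses the SAM output; the production backend.

Alignments are categorized by mapping score (SAM MAPQ): ``unique`` when the
score is strictly over the cutoff (20 for aln, 30 for mem), ``multi``
otherwise, ``unmapped`` when there is no alignment.  Iterative mapping
re-aligns only the previous round's unmapped reads while raising the
allowed edit distance by one per round, which rescues reads carrying SNPs
or sequencing errors.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._seq import FastqRecord, encode, revcomp, write_fastq

__all__ = [
    "MappingParams",
    "TagAlignment",
    "MismatchScanAligner",
    "BwaAligner",
    "categorize",
    "map_chunked",
    "iterative_map",
    "write_alignment_table",
    "read_alignment_table",
]

UNIQUE_CUTOFF = {"aln": 20, "mem": 30}


@dataclass
class MappingParams:
    algorithm: str = "aln"  # "mem" when ReadsType is "long"
    iterative: bool = False
    n_max: int = 3
    chunk_size: int = 100_000
    threads: int = 1

    def __post_init__(self) -> None:
        if self.algorithm not in UNIQUE_CUTOFF:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.n_max < 0:
            raise ValueError("n_max must be >= 0")

    @property
    def unique_score_cutoff(self) -> int:
        return UNIQUE_CUTOFF[self.algorithm]


class RawHit(NamedTuple):
    """One aligner answer per read; chrom is None for unmapped reads."""

    read_id: str
    chrom: str | None
    pos: int  # 0-based leftmost mapped coordinate
    end: int  # exclusive
    strand: str
    score: int  # SAM MAPQ


@dataclass(frozen=True)
class TagAlignment:
    read_id: str
    side: str  # "left" | "right"
    chrom: str | None
    pos: int
    end: int
    strand: str
    score: int
    category: str  # unique | multi | unmapped
    n_used: int = 0


def categorize(score: int, mapped: bool, params: MappingParams) -> str:
    """Mapping-score category: unique strictly over the cutoff, else multi."""
    if not mapped:
        return "unmapped"
    return "unique" if score > params.unique_score_cutoff else "multi"


class MismatchScanAligner:
    """Exhaustive ≤n-mismatch aligner over an in-memory genome.

    Every length-L window on both strands is compared against the read
    (2-bit packed, popcount mismatch counting).  A read is reported with
    MAPQ 37 when exactly one window achieves the minimum mismatch count
    (unique), MAPQ 0 when several do (multi-mapped), and as unmapped when
    no window is within the allowed edit distance.  Gaps are not modeled.
    """

    MAPQ_UNIQUE = 37

    def __init__(self, genome: dict[str, str]):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._codes = {c: encode(s) for c, s in self.genome.items()}
        self._window_cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    def _windows(self, chrom: str, length: int) -> tuple[np.ndarray, np.ndarray]:
        key = (chrom, length)
        if key not in self._window_cache:
            codes = self._codes[chrom]
            n_win = len(codes) - length + 1
            if n_win <= 0:
                packed = np.zeros(0, dtype=np.uint64)
                valid = np.zeros(0, dtype=bool)
            else:
                packed = np.zeros(n_win, dtype=np.uint64)
                invalid = np.zeros(n_win, dtype=bool)
                for k in range(length):
                    col = codes[k : k + n_win]
                    invalid |= col == 4
                    packed |= (col.astype(np.uint64) & np.uint64(3)) << np.uint64(2 * k)
                valid = ~invalid
            self._window_cache[key] = (packed, valid)
        return self._window_cache[key]

    @staticmethod
    def _pack(seq: str) -> np.ndarray | None:
        codes = encode(seq)
        if (codes == 4).any():
            return None
        packed = np.uint64(0)
        for k, c in enumerate(codes):
            packed |= np.uint64(int(c)) << np.uint64(2 * k)
        return packed

    def _hits(self, seq: str, max_mm: int) -> list[tuple[int, str, int, str]]:
        """(mismatches, chrom, pos, strand) for all windows within max_mm."""
        length = len(seq)
        if length == 0 or length > 32:
            return []
        out = []
        lo_mask = np.uint64(int("01" * length, 2))
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            q = self._pack(query)
            if q is None:
                continue
            for chrom in self.genome:
                packed, valid = self._windows(chrom, length)
                if len(packed) == 0:
                    continue
                x = packed ^ q
                mm = np.bitwise_count((x | (x >> np.uint64(1))) & lo_mask)
                ok = valid & (mm <= max_mm)
                for pos in np.nonzero(ok)[0]:
                    out.append((int(mm[pos]), chrom, int(pos), strand))
        return out

    def align(self, reads: Sequence[FastqRecord], max_edit_distance: int) -> list[RawHit]:
        hits = []
        for rec in reads:
            found = self._hits(rec.seq, max_edit_distance)
            if not found:
                hits.append(RawHit(rec.read_id, None, -1, -1, ".", 0))
                continue
            best_mm = min(h[0] for h in found)
            best = sorted(h for h in found if h[0] == best_mm)
            mm, chrom, pos, strand = best[0]
            score = self.MAPQ_UNIQUE if len(best) == 1 else 0
            hits.append(
                RawHit(rec.read_id, chrom, pos, pos + len(rec.seq), strand, score)
            )
        return hits


class BwaAligner:
    """Backend shelling out to bwa (aln/samse for short tags, mem for long)."""

    def __init__(self, genome_fasta: str | Path, algorithm: str = "aln",
                 executable: str = "bwa", threads: int = 1):
        self.genome_fasta = Path(genome_fasta)
        self.algorithm = algorithm
        self.executable = executable
        self.threads = threads
        if shutil.which(executable) is None:
            raise FileNotFoundError(f"aligner executable {executable!r} not found")
        if not (self.genome_fasta.with_suffix(self.genome_fasta.suffix + ".bwt")).exists():
            self._run([executable, "index", str(self.genome_fasta)])

    @staticmethod
    def _run(cmd: list[str], **kw) -> subprocess.CompletedProcess:
        proc = subprocess.run(cmd, capture_output=True, **kw)
        if proc.returncode != 0:
            raise RuntimeError(
                f"aligner failed ({' '.join(cmd[:2])}): {proc.stderr.decode()[-500:]}"
            )
        return proc

    def align(self, reads: Sequence[FastqRecord], max_edit_distance: int) -> list[RawHit]:
        import pysam

        with tempfile.TemporaryDirectory() as tmp:
            fq = Path(tmp) / "tags.fq"
            write_fastq(fq, reads)
            sam_path = Path(tmp) / "tags.sam"
            if self.algorithm == "aln":
                sai = Path(tmp) / "tags.sai"
                proc = self._run(
                    [self.executable, "aln", "-n", str(max_edit_distance),
                     "-t", str(self.threads), str(self.genome_fasta), str(fq)]
                )
                sai.write_bytes(proc.stdout)
                proc = self._run(
                    [self.executable, "samse", str(self.genome_fasta),
                     str(sai), str(fq)]
                )
            else:
                proc = self._run(
                    [self.executable, "mem", "-t", str(self.threads),
                     str(self.genome_fasta), str(fq)]
                )
            sam_path.write_bytes(proc.stdout)
            by_id: dict[str, RawHit] = {}
            with pysam.AlignmentFile(str(sam_path), "r") as sam:
                for rec in sam:
                    if rec.is_secondary or rec.is_supplementary:
                        continue
                    if rec.is_unmapped:
                        by_id[rec.query_name] = RawHit(rec.query_name, None, -1, -1, ".", 0)
                    else:
                        by_id[rec.query_name] = RawHit(
                            rec.query_name,
                            rec.reference_name,
                            rec.reference_start,
                            rec.reference_end,
                            "-" if rec.is_reverse else "+",
                            rec.mapping_quality,
                        )
        return [
            by_id.get(r.read_id, RawHit(r.read_id, None, -1, -1, ".", 0))
            for r in reads
        ]


def _to_alignment(hit: RawHit, side: str, params: MappingParams, n_used: int) -> TagAlignment:
    mapped = hit.chrom is not None
    return TagAlignment(
        read_id=hit.read_id,
        side=side,
        chrom=hit.chrom,
        pos=hit.pos,
        end=hit.end,
        strand=hit.strand,
        score=hit.score,
        category=categorize(hit.score, mapped, params),
        n_used=n_used,
    )


def map_chunked(tags: Iterable[FastqRecord], params: MappingParams, aligner,
                side: str = "left", max_edit_distance: int = 0,
                n_used: int = 0) -> list[TagAlignment]:
    """Map tags chunk by chunk; output canonicalized by read_id.

    The result is a read_id-sorted list independent of chunk size, so a run
    split across chunks (or threads inside the aligner backend) is
    reproducible.
    """
    tags = list(tags)
    out: list[TagAlignment] = []
    for i in range(0, len(tags), params.chunk_size):
        chunk = tags[i : i + params.chunk_size]
        for hit in aligner.align(chunk, max_edit_distance):
            out.append(_to_alignment(hit, side, params, n_used))
    if len(out) != len(tags):
        raise RuntimeError("aligner did not return one hit per read")
    out.sort(key=lambda a: a.read_id)
    return out


def iterative_map(tags: Iterable[FastqRecord], params: MappingParams, aligner,
                  side: str = "left") -> list[TagAlignment]:
    """Iteratively re-map unmapped reads at increasing edit distance.

    Round k allows k-1 mismatches; only reads still unmapped re-enter.
    Stops when no unmapped reads remain or the n_max cap is reached.  The
    unique count is non-decreasing in the number of rounds.
    """
    tags = list(tags)
    if not params.iterative:
        return map_chunked(tags, params, aligner, side, max_edit_distance=0)
    remaining = tags
    merged: dict[str, TagAlignment] = {}
    n = 0
    while remaining and n <= params.n_max:
        result = map_chunked(remaining, params, aligner, side,
                             max_edit_distance=n, n_used=n)
        next_round = []
        by_id = {r.read_id: r for r in remaining}
        for aln in result:
            if aln.category == "unmapped" and n < params.n_max:
                next_round.append(by_id[aln.read_id])
            else:
                merged[aln.read_id] = aln
        remaining = next_round
        n += 1
    out = sorted(merged.values(), key=lambda a: a.read_id)
    if len(out) != len(tags):
        raise RuntimeError("iterative mapping lost reads")
    return out


_COLUMNS = ["read_id", "side", "chrom", "pos", "end", "strand", "score",
            "category", "n_used"]


def write_alignment_table(path: str | Path, alignments: Sequence[TagAlignment]) -> None:
    df = pd.DataFrame([a.__dict__ for a in alignments], columns=_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_alignment_table(path: str | Path) -> list[TagAlignment]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    out = []
    for row in df.itertuples(index=False):
        chrom = None if (isinstance(row.chrom, float) or row.chrom == "") else str(row.chrom)
        out.append(TagAlignment(str(row.read_id), row.side, chrom, int(row.pos),
                                int(row.end), row.strand, int(row.score),
                                row.category, int(row.n_used)))
    return out
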