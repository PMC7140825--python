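"""Raw-read preprocessing: adapters, linkers, tag splitting, discovery.

A DLO Hi-C read is an ~80-bp construct — a ~20-bp genomic tag, a ~40-bp
full linker, a second tag — followed by sequencing adapter.  This module

* enumerates full linkers from one or two half-linkers (combinations
  AA/AB/BA/BB; a single half-linker, the in situ protocol, yields AA only),
* detects the adapter by positional base-frequency consensus over a sample
  of linker-anchored reads and trims it,
* locates the best-scoring linker in each read by local alignment and
  splits reads into per-linker-type tag pairs,
* and, when neither linker nor enzyme is configured, discovers both de
  novo from sequence overrepresentation.

Full-linker assembly: two half-linkers ligate head-to-head on opposite
strands, so combination XY is assembled as ``halfX + revcomp(halfY)``; the
plain concatenation ``halfX + halfY`` is also scored as an alternate
candidate per read and whichever scores higher wins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._seq import FastqRecord, encode, is_nucleotide, revcomp, write_fastq
from .align import local_align_batch
from .fragments import RestrictionSite

__all__ = [
    "LinkerAlignParams",
    "AdapterParams",
    "FullLinker",
    "LinkerSet",
    "LinkerHit",
    "DetectionError",
    "enumerate_full_linkers",
    "detect_adapter_consensus",
    "trim_adapter",
    "align_linker",
    "align_linker_batch",
    "split_by_linker",
    "discover_linker_and_site",
]

TYPE_ORDER = {"AA": 0, "AB": 1, "BA": 2, "BB": 3}


class DetectionError(RuntimeError):
    """Automatic linker/enzyme detection found no overrepresented sequence."""


@dataclass
class LinkerAlignParams:
    match_score: int = 1
    mismatch_score: int = -1
    indel_score: int = -1
    min_score_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch_score > 0 or self.indel_score > 0:
            raise ValueError("mismatch/indel scores must be <= 0")
        if not 0 < self.min_score_fraction <= 1:
            raise ValueError("min_score_fraction must be in (0, 1]")


@dataclass
class AdapterParams:
    sample_size: int = 100
    min_base_frequency: float = 0.6
    min_overlap: int = 6


@dataclass(frozen=True)
class FullLinker:
    type_label: str  # AA | AB | BA | BB
    sequence: str
    variant: str  # "rc" (halfX + revcomp(halfY)) or "cat" (halfX + halfY)


@dataclass
class LinkerSet:
    half_linkers: dict[str, str]
    full_linkers: list[FullLinker] = field(default_factory=list)

    @property
    def protocol(self) -> str:
        return "in-situ-DLO" if len(self.half_linkers) == 1 else "DLO"

    @property
    def type_labels(self) -> list[str]:
        return sorted({f.type_label for f in self.full_linkers}, key=TYPE_ORDER.get)


@dataclass
class LinkerHit:
    """Per-read linker location record (one row of the preprocess table)."""

    left_tag: str
    linker_start: int
    linker_end: int
    right_tag: str
    adapter_start: int | None
    linker_type: str
    align_score: int
    read_id: str
    read_seq: str
    orientation: str  # forward | reverse
    qualities: str


def enumerate_full_linkers(half_linkers: Sequence[str]) -> LinkerSet:
    """All full-linker combinations from one or two half-linkers."""
    if not 1 <= len(half_linkers) <= 2:
        raise ValueError(
            f"{len(half_linkers)} half-linkers given; the protocol uses 1 or 2"
        )
    for h in half_linkers:
        if not is_nucleotide(h):
            raise ValueError(f"half-linker {h!r} is not a nucleotide string")
    labels = "A" if len(half_linkers) == 1 else "AB"
    halves = dict(zip(labels, half_linkers))
    if len(half_linkers) == 2 and half_linkers[0] == half_linkers[1]:
        raise ValueError("two identical half-linkers; supply just one")
    full = []
    for x in labels:
        for y in labels:
            seen = set()
            for variant, seq in (
                ("rc", halves[x] + revcomp(halves[y])),
                ("cat", halves[x] + halves[y]),
            ):
                if seq not in seen:
                    full.append(FullLinker(x + y, seq, variant))
                    seen.add(seq)
    return LinkerSet(halves, full)


def _candidates(linkers: LinkerSet) -> list[tuple[str, str, str, str]]:
    """(type, sequence, orientation, variant) in deterministic priority order.

    Priority (used for exact tie-breaks): linker type AA<AB<BA<BB, then the
    head-to-head assembly before the plain concatenation, then forward
    before reverse orientation.  Duplicate sequences keep their
    highest-priority labeling only.
    """
    if not linkers.full_linkers:
        raise ValueError("empty linker set")
    variant_order = {"rc": 0, "cat": 1}
    ordered = sorted(
        linkers.full_linkers,
        key=lambda f: (TYPE_ORDER[f.type_label], variant_order[f.variant]),
    )
    out: list[tuple[str, str, str, str]] = []
    seen: set[str] = set()
    for orient in ("forward", "reverse"):
        for f in ordered:
            seq = f.sequence if orient == "forward" else revcomp(f.sequence)
            if seq not in seen:
                out.append((f.type_label, seq, orient, f.variant))
                seen.add(seq)
    # re-sort so type order dominates orientation for distinct sequences
    out.sort(key=lambda c: (TYPE_ORDER[c[0]], variant_order[c[3]],
                            0 if c[2] == "forward" else 1))
    return out


def align_linker_batch(
    reads: Sequence[FastqRecord],
    linkers: LinkerSet,
    params: LinkerAlignParams | None = None,
    adapter_starts: Sequence[int | None] | None = None,
) -> list[LinkerHit | None]:
    """Best linker hit per read, or None when no candidate reaches threshold.

    Every full-linker candidate (both assembly variants, both orientations)
    is locally aligned against every read; a hit is accepted when its score
    is at least ``min_score_fraction`` of the candidate's full length.
    Ties go to the earlier linker start, then candidate priority order.
    """
    params = params or LinkerAlignParams()
    cands = _candidates(linkers)
    seqs = [r.seq for r in reads]
    n = len(reads)
    best_score = np.full(n, -1, dtype=np.int64)
    best_start = np.zeros(n, dtype=np.int64)
    best_end = np.zeros(n, dtype=np.int64)
    best_cand = np.full(n, -1, dtype=np.int64)
    for ci, (_t, cseq, _o, _v) in enumerate(cands):
        res = local_align_batch(seqs, cseq, params.match_score,
                                params.mismatch_score, params.indel_score)
        score = res[:, 0].copy()
        threshold = params.min_score_fraction * len(cseq)
        score[score < threshold] = -1
        upd = (score > best_score) | (
            (score == best_score) & (score >= 0) & (res[:, 1] < best_start)
        )
        best_score = np.where(upd, score, best_score)
        best_start = np.where(upd, res[:, 1], best_start)
        best_end = np.where(upd, res[:, 2], best_end)
        best_cand = np.where(upd, ci, best_cand)
    hits: list[LinkerHit | None] = []
    for i, rec in enumerate(reads):
        if best_cand[i] < 0:
            hits.append(None)
            continue
        t, _cseq, orient, _v = cands[best_cand[i]]
        start, end = int(best_start[i]), int(best_end[i])
        a_start = adapter_starts[i] if adapter_starts is not None else None
        hits.append(
            LinkerHit(
                left_tag=rec.seq[:start],
                linker_start=start,
                linker_end=end,
                right_tag=rec.seq[end : a_start if a_start is not None else len(rec.seq)],
                adapter_start=a_start,
                linker_type=t,
                align_score=int(best_score[i]),
                read_id=rec.read_id,
                read_seq=rec.seq,
                orientation=orient,
                qualities=rec.qual,
            )
        )
    return hits


def align_linker(
    read: str | FastqRecord,
    linkers: LinkerSet,
    params: LinkerAlignParams | None = None,
) -> LinkerHit | None:
    """Locate the best-scoring full linker in one read."""
    if isinstance(read, str):
        read = FastqRecord("read", read, "I" * len(read))
    shortest = min(len(f.sequence) for f in linkers.full_linkers)
    if len(read.seq) <= shortest:
        return None
    return align_linker_batch([read], linkers, params)[0]


def detect_adapter_consensus(
    reads: Sequence[FastqRecord],
    linkers: LinkerSet,
    params: AdapterParams | None = None,
    align_params: LinkerAlignParams | None = None,
) -> str | None:
    """Consensus adapter sequence from linker-anchored positional counts.

    Reads are anchored at their detected linker end; per downstream
    position the most frequent base is called when its frequency (among
    reads covering the position) reaches ``min_base_frequency``.  The
    adapter is the first called run of at least ``min_overlap`` bases —
    the genomic tag directly after the linker is random across reads, so
    only the adapter (and the few conserved cut-site bases, too short to
    qualify) forms a run.  Returns None when no such run exists.
    """
    params = params or AdapterParams()
    if not reads:
        raise ValueError("no reads supplied for adapter detection")
    sample = list(reads[: params.sample_size])
    hits = align_linker_batch(sample, linkers, align_params)
    tails = [
        rec.seq[h.linker_end :]
        for rec, h in zip(sample, hits)
        if h is not None and h.orientation == "forward"
    ]
    if not tails:
        return None
    width = max(len(t) for t in tails)
    mat = np.full((len(tails), width), 4, dtype=np.uint8)
    for i, t in enumerate(tails):
        mat[i, : len(t)] = encode(t)
    called: list[str | None] = []
    for j in range(width):
        col = mat[:, j]
        cover = col < 4
        n_cover = int(cover.sum())
        if n_cover < max(5, 0.5 * len(tails)):
            called.append(None)
            continue
        counts = np.bincount(col[cover], minlength=4)[:4]
        top = int(np.argmax(counts))
        if counts[top] / n_cover >= params.min_base_frequency:
            called.append("ACGT"[top])
        else:
            called.append(None)
    run = []
    for c in called:
        if c is None:
            if len(run) >= params.min_overlap:
                return "".join(run)
            run = []
        else:
            run.append(c)
    if len(run) >= params.min_overlap:
        return "".join(run)
    return None


def _adapter_match_at(seq: str, adapter: str, start: int, min_overlap: int) -> bool:
    overlap = min(len(adapter), len(seq) - start)
    if overlap < min_overlap:
        return False
    mismatches = sum(a != b for a, b in zip(seq[start : start + overlap], adapter))
    return mismatches <= overlap // 8


def trim_adapter(
    read: FastqRecord, adapter: str, params: AdapterParams | None = None
) -> tuple[FastqRecord, int | None]:
    """Clip the adapter from a read; identity when the adapter is empty.

    The earliest position where the adapter prefix matches with at least
    ``min_overlap`` overlap and at most one mismatch per 8 bases is taken
    as the adapter start (an earlier start implies a longer overlap, so a
    long clean match always dominates spurious short ones).
    """
    params = params or AdapterParams()
    if not adapter:
        return read, None
    for s in range(len(read.seq) - params.min_overlap + 1):
        if _adapter_match_at(read.seq, adapter, s, params.min_overlap):
            return FastqRecord(read.read_id, read.seq[:s], read.qual[:s]), s
    return read, None


def trim_adapter_batch(
    reads: Sequence[FastqRecord], adapter: str, params: AdapterParams | None = None
) -> tuple[list[FastqRecord], list[int | None]]:
    """Vectorized adapter clipping for a batch of reads.

    A 16-bp seed window (2-mismatch tolerance) proposes candidate starts,
    which are then verified with the same full-overlap rule as
    :func:`trim_adapter`.
    """
    params = params or AdapterParams()
    if not adapter or not reads:
        return list(reads), [None] * len(reads)
    seed_len = min(16, len(adapter))
    seed = encode(adapter[:seed_len])
    lengths = np.fromiter((len(r.seq) for r in reads), dtype=np.int64)
    out_reads: list[FastqRecord] = list(reads)
    starts: list[int | None] = [None] * len(reads)
    for length in np.unique(lengths):
        idx = np.nonzero(lengths == length)[0]
        if length < params.min_overlap:
            continue
        mat = np.empty((len(idx), length), dtype=np.uint8)
        for row, k in enumerate(idx):
            mat[row] = encode(reads[k].seq)
        found = np.full(len(idx), -1, dtype=np.int64)
        for s in range(length - params.min_overlap + 1):
            w = min(seed_len, length - s)
            mm = (mat[:, s : s + w] != seed[:w]).sum(axis=1)
            # any position passing the full-overlap rule has at most
            # overlap//8 mismatches in the seed window too, so this
            # candidate filter is complete; verification below is exact
            tol = min(len(adapter), length - s) // 8
            cand = (found < 0) & (mm <= tol)
            for row in np.nonzero(cand)[0]:
                rec = reads[idx[row]]
                if _adapter_match_at(rec.seq, adapter, s, params.min_overlap):
                    found[row] = s
        for row, k in enumerate(idx):
            s = int(found[row])
            if s >= 0:
                rec = reads[k]
                out_reads[k] = FastqRecord(rec.read_id, rec.seq[:s], rec.qual[:s])
                starts[k] = s
    return out_reads, starts


def split_by_linker(
    records_and_hits: Iterable[tuple[FastqRecord, LinkerHit | None]],
    out_dir: str | Path,
    min_tag_length: int = 10,
    compress: bool = True,
) -> dict:
    """Write per-linker-type tag-pair FASTQ files plus the hit table.

    Reads with no hit fall into ``no_linker``; reads whose left or right
    tag is shorter than ``min_tag_length`` fall into ``short_tag``.
    Category counts sum to the number of input reads.  Reverse-orientation
    hits are re-oriented so that the written r1/r2 tags always read
    left-to-right across the original construct.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fq.gz" if compress else ".fq"
    writers: dict[str, tuple[list[FastqRecord], list[FastqRecord]]] = {}
    counts: Counter = Counter()
    table_rows = []
    for rec, hit in records_and_hits:
        counts["total"] += 1
        if hit is None:
            counts["no_linker"] += 1
            continue
        table_rows.append(hit)
        left, right = hit.left_tag, hit.right_tag
        lq = hit.qualities[: hit.linker_start]
        rq = hit.qualities[hit.linker_end : hit.linker_end + len(right)]
        if hit.orientation == "reverse":
            left, right = revcomp(right), revcomp(left)
            lq, rq = rq[::-1], lq[::-1]
        if len(left) < min_tag_length or len(right) < min_tag_length:
            counts["short_tag"] += 1
            continue
        counts[hit.linker_type] += 1
        r1, r2 = writers.setdefault(hit.linker_type, ([], []))
        r1.append(FastqRecord(rec.read_id, left, lq))
        r2.append(FastqRecord(rec.read_id, right, rq))
    for t, (r1, r2) in writers.items():
        write_fastq(out_dir / f"{t}.r1{suffix}", r1)
        write_fastq(out_dir / f"{t}.r2{suffix}", r2)
    with open(out_dir / "linker_hits.tsv", "w") as fh:
        fh.write("left_tag\tlinker_start\tlinker_end\tright_tag\tadapter_start"
                 "\tlinker_type\talign_score\tread_id\tread_seq\torientation"
                 "\tqualities\n")
        for h in table_rows:
            a = "" if h.adapter_start is None else h.adapter_start
            fh.write(f"{h.left_tag}\t{h.linker_start}\t{h.linker_end}\t"
                     f"{h.right_tag}\t{a}\t{h.linker_type}\t{h.align_score}\t"
                     f"{h.read_id}\t{h.read_seq}\t{h.orientation}\t{h.qualities}\n")
    counts.setdefault("no_linker", 0)
    counts.setdefault("short_tag", 0)
    return {"files": {t: [f"{t}.r1{suffix}", f"{t}.r2{suffix}"] for t in writers},
            "counts": dict(counts)}


# ---------------------------------------------------------------------------
# De novo discovery of linker and restriction site
# ---------------------------------------------------------------------------

def _is_rc_palindrome(seq: str) -> bool:
    return len(seq) > 0 and len(seq) % 2 == 0 and revcomp(seq) == seq


def _cluster_consensus(sample: list[str], seed: str,
                       min_freq: float, max_members: int = 2000) -> tuple[str, int]:
    """Positional consensus of reads containing ``seed`` (either strand).

    Reads are oriented so the seed matches forward, anchored at its first
    occurrence, and per-column base frequencies are called at ``min_freq``.
    Returns the maximal called run containing the seed and the member count.
    """
    members: list[tuple[str, int]] = []
    for seq in sample:
        p = seq.find(seed)
        if p < 0:
            rc = revcomp(seq)
            p = rc.find(seed)
            if p < 0:
                continue
            seq = rc
        members.append((seq, p))
        if len(members) >= max_members:
            break
    if not members:
        return "", 0
    left_span = max(p for _s, p in members)
    right_span = max(len(s) - p for s, p in members)
    width = left_span + right_span
    mat = np.full((len(members), width), 4, dtype=np.uint8)
    for i, (seq, p) in enumerate(members):
        off = left_span - p
        mat[i, off : off + len(seq)] = encode(seq)
    called: list[str | None] = []
    for j in range(width):
        col = mat[:, j]
        cover = col < 4
        n_cover = int(cover.sum())
        if n_cover < max(5, 0.3 * len(members)):
            called.append(None)
            continue
        counts = np.bincount(col[cover], minlength=4)[:4]
        top = int(np.argmax(counts))
        called.append("ACGT"[top] if counts[top] / n_cover >= min_freq else None)
    # maximal called run containing the seed anchor column
    anchor = left_span
    lo = anchor
    while lo > 0 and called[lo - 1] is not None:
        lo -= 1
    hi = anchor
    while hi < width and called[hi] is not None:
        hi += 1
    if hi <= lo:
        return "", len(members)
    return "".join(called[lo:hi]), len(members)  # type: ignore[arg-type]


def _site_candidates(consensus: str, min_middle: int = 16) -> list[tuple[str, int, str]]:
    """(site, cut_offset, middle) splits consistent with a symmetric cutter.

    The conserved consensus is cut-site-left-remnant + full linker +
    cut-site-right-remnant; the recognition sequence must be a
    reverse-complement palindrome cut symmetrically (cut offset a with
    1 <= a <= n/2), and the remaining middle (the full linker) must have
    even length.
    """
    out = []
    for n in (4, 6, 8):
        for a in range(1, n // 2 + 1):
            b = n - a
            if a + b >= len(consensus) - min_middle:
                continue
            site = consensus[:a] + consensus[len(consensus) - b :]
            middle = consensus[a : len(consensus) - b]
            if len(middle) % 2 == 0 and _is_rc_palindrome(site):
                out.append((site, a, middle))
    return out


def discover_linker_and_site(
    reads: Iterable[FastqRecord | str],
    sample_size: int = 10_000,
    k: int = 12,
    min_base_frequency: float = 0.6,
    min_seed_fraction: float = 0.05,
) -> tuple[list[str], str]:
    """Recover half-linker sequence(s) and the restriction site de novo.

    The most frequent k-mers of a read sample seed consensus clusters; each
    cluster's conserved run is split into cut-site remnants plus a full
    linker under the symmetric-cutter constraints of
    :func:`_site_candidates`.  Homodimer linkers (AA/BB) are
    reverse-complement palindromes ``h + revcomp(h)``, which pins down the
    half-linkers; clusters from distinct half-linkers must agree on the
    site.  Returns (half-linkers ordered by cluster abundance, site in
    caret notation).  Raises :class:`DetectionError` when nothing is
    overrepresented (e.g. on non-DLO input).
    """
    sample: list[str] = []
    for rec in reads:
        sample.append(rec if isinstance(rec, str) else rec.seq)
        if len(sample) >= sample_size:
            break
    if len(sample) < 100:
        raise DetectionError("too few reads for linker detection")
    counts: Counter = Counter()
    for seq in sample:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    threshold = min_seed_fraction * len(sample)
    seeds = [km for km, c in counts.most_common(200) if c >= threshold]
    if not seeds:
        raise DetectionError(
            "no overrepresented k-mer found; configure the linker manually"
        )

    consensi: list[str] = []  # every consensus seen, for seed masking
    validated: list[tuple[str, int, list[tuple[str, int, str]]]] = []
    read_len = max(len(s) for s in sample)
    attempts = 0
    for seed in seeds:
        if attempts >= 15:
            break
        if any(seed in c or seed in revcomp(c) for c in consensi):
            continue
        attempts += 1
        consensus, n_members = _cluster_consensus(sample, seed, min_base_frequency)
        if not consensus:
            continue
        consensi.append(consensus)
        # the adapter run reaches the read end in nearly every read; a
        # linker consensus is interior.  Skip clusters longer than 2/3 read.
        if len(consensus) > 2 * read_len / 3:
            continue
        cands = _site_candidates(consensus)
        if cands:
            validated.append((consensus, n_members, cands))

    if not validated:
        raise DetectionError(
            "no conserved region with restriction-site structure found"
        )

    # choose the (site, cut) split shared by all validated clusters,
    # preferring splits supported by a homodimer (rc-palindromic) middle
    split_votes: dict[tuple[str, int], list[tuple[int, str]]] = {}
    for _cons, n_members, cands in validated:
        for site, a, middle in cands:
            split_votes.setdefault((site, a), []).append((n_members, middle))
    def _score(item):
        (site, a), middles = item
        homo = sum(1 for _n, m in middles if _is_rc_palindrome(m))
        return (len(middles), homo, -len(site))
    (site, cut), middles = max(split_votes.items(), key=_score)
    if not any(_is_rc_palindrome(m) for _n, m in middles):
        raise DetectionError("no homodimer linker cluster found")

    halves: list[str] = []
    for n_members, middle in sorted(middles, key=lambda t: -t[0]):
        if _is_rc_palindrome(middle):
            h = middle[: len(middle) // 2]
            if h not in halves:
                halves.append(h)
    halves = halves[:2]
    rs = RestrictionSite(site, cut)
    return halves, str(rs)
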