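"""In silico restriction digestion and fragment lookup.

A restriction site is written with a caret marking the cut, e.g. ``T^TAA``
(MseI) or ``A^AGCTT`` (HindIII).  Digesting a genome cuts every
forward-strand occurrence of the recognition sequence at
``match_start + cut_offset``; chromosome ends close the first and last
fragments so fragments tile each chromosome without gaps or overlaps.

Only forward-strand matches are scanned.  The sites this protocol uses are
reverse-complement palindromes, for which forward scanning is exact; a
non-palindromic site would additionally require the reverse strand and is
not supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._seq import is_nucleotide

__all__ = [
    "RestrictionSite",
    "FragmentIndex",
    "digest_genome",
    "assign_fragment",
    "strand_end_table",
]


@dataclass(frozen=True)
class RestrictionSite:
    """Recognition sequence plus the cut offset within it."""

    sequence: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not is_nucleotide(self.sequence):
            raise ValueError(f"invalid recognition sequence {self.sequence!r}")
        if not 0 <= self.cut_offset <= len(self.sequence):
            raise ValueError("cut offset outside recognition sequence")

    @classmethod
    def from_string(cls, text: str) -> "RestrictionSite":
        """Parse caret notation, e.g. ``T^TAA`` -> (TTAA, cut 1)."""
        if text.count("^") != 1:
            raise ValueError(
                f"restriction site {text!r} must contain exactly one '^'"
            )
        left, right = text.split("^")
        return cls(left + right, len(left))

    def __str__(self) -> str:
        return f"{self.sequence[:self.cut_offset]}^{self.sequence[self.cut_offset:]}"

    @property
    def overhang(self) -> int:
        """Length of the 5' overhang left by a symmetric cutter."""
        return len(self.sequence) - 2 * self.cut_offset


@dataclass
class FragmentIndex:
    """Per-chromosome restriction fragments with ordinal indices.

    ``starts[chrom]`` holds fragment start coordinates (the first is 0);
    fragment ``k`` spans ``[starts[k], ends[k])`` and ordinals are
    consecutive within a chromosome.
    """

    site: RestrictionSite
    chrom_sizes: dict[str, int]
    starts: dict[str, np.ndarray] = field(repr=False)

    def n_fragments(self, chrom: str) -> int:
        return len(self.starts[chrom])

    def bounds(self, chrom: str, ordinal: int) -> tuple[int, int]:
        s = self.starts[chrom]
        start = int(s[ordinal])
        end = int(s[ordinal + 1]) if ordinal + 1 < len(s) else self.chrom_sizes[chrom]
        return start, end

    def cut_positions(self, chrom: str) -> np.ndarray:
        """Internal cut coordinates (fragment boundaries, chromosome ends excluded)."""
        return self.starts[chrom][1:]

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, s in self.starts.items():
                size = self.chrom_sizes[chrom]
                ends = np.append(s[1:], size)
                for k, (a, b) in enumerate(zip(s, ends)):
                    fh.write(f"{chrom}\t{a}\t{b}\t{k}\n")

    @classmethod
    def from_bed(cls, path: str | Path, site: RestrictionSite) -> "FragmentIndex":
        starts: dict[str, list[int]] = {}
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                chrom, a, b, _k = line.rstrip("\n").split("\t")
                starts.setdefault(chrom, []).append(int(a))
                sizes[chrom] = int(b)
        return cls(site, sizes, {c: np.asarray(v, dtype=np.int64) for c, v in starts.items()})


def digest_genome(genome: dict[str, str], site: RestrictionSite) -> FragmentIndex:
    """Cut every forward-strand site occurrence; overlapping matches count."""
    starts: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    pattern = re.compile(f"(?={re.escape(site.sequence)})")
    for chrom, seq in genome.items():
        seq = seq.upper()
        cuts = [m.start() + site.cut_offset for m in pattern.finditer(seq)]
        # cuts at coordinate 0 or len(seq) would create empty fragments
        cuts = [c for c in cuts if 0 < c < len(seq)]
        starts[chrom] = np.asarray([0] + sorted(set(cuts)), dtype=np.int64)
        sizes[chrom] = len(seq)
    return FragmentIndex(site, sizes, starts)


def assign_fragment(index: FragmentIndex, chrom: str, five_prime_pos: int) -> int:
    """Ordinal of the fragment containing a tag's 5'-most mapped base."""
    size = index.chrom_sizes[chrom]
    if not 0 <= five_prime_pos < size:
        raise ValueError(
            f"position {chrom}:{five_prime_pos} outside chromosome (size {size})"
        )
    s = index.starts[chrom]
    return int(np.searchsorted(s, five_prime_pos, side="right") - 1)


def five_prime_coordinate(pos: int, end: int, strand: str) -> int:
    """5'-most mapped base of an alignment spanning [pos, end)."""
    return pos if strand == "+" else end - 1


def end_label(index: FragmentIndex, chrom: str, ordinal: int, five_prime_pos: int) -> str:
    """'s' when the 5'-most base sits in the fragment's 5' half (ties -> 's')."""
    start, end = index.bounds(chrom, ordinal)
    return "s" if (five_prime_pos - start) <= (end - 1 - five_prime_pos) else "t"


STRAND_COMBOS = [("+", "+"), ("+", "-"), ("-", "+"), ("-", "-")]
END_COMBOS = [("s", "s"), ("s", "t"), ("t", "s"), ("t", "t")]


def strand_end_table(pairs: Iterable, index: FragmentIndex) -> pd.DataFrame:
    """4x4 strand-combination x fragment-end-combination counts.

    Rows are (strandL, strandR), columns (endL, endR); 's' marks a tag whose
    5'-most base lies in the 5' half of its restriction fragment, 't' the 3'
    half.  Counts sum to the number of input pairs.
    """
    table = pd.DataFrame(
        0,
        index=[f"{a},{b}" for a, b in STRAND_COMBOS],
        columns=[f"{a},{b}" for a, b in END_COMBOS],
        dtype=np.int64,
    )
    for p in pairs:
        labels = []
        for tag, frag in ((p.tag_l, p.frag_l), (p.tag_r, p.frag_r)):
            fp = five_prime_coordinate(tag.pos, tag.end, tag.strand)
            labels.append(end_label(index, tag.chrom, frag, fp))
        table.loc[f"{p.tag_l.strand},{p.tag_r.strand}", f"{labels[0]},{labels[1]}"] += 1
    return table
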