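"""Pairing, noise classification and duplicate removal.

Uniquely mapped left/right tags sharing a read identifier form a pair;
unpaired tags (singletons) are discarded.  Pairs are then classified:

* ``heterodimer`` — mixed linker type (AB/BA); gauges random ligation;
* ``self_ligation`` — both tags in the same restriction fragment (the two
  ends of one fragment ligated around one linker);
* ``re_ligation`` — tags in ordinally adjacent fragments (re-joined at
  their shared cut site);
* ``valid`` — everything else; only these feed the contact matrix.

Precedence is heterodimer > self_ligation > re_ligation > valid.  PCR
duplicates are pairs whose two ends map on the same strands within a 2-bp
window end-for-end; duplicate clusters are built by single linkage over
the position-sorted stream and the first pair of each cluster is kept.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .fragments import FragmentIndex, assign_fragment, five_prime_coordinate
from .mapping import TagAlignment

__all__ = [
    "PairClassParams",
    "PairRecord",
    "join_pairs",
    "classify_pair",
    "deduplicate",
    "summarize_pairs",
    "write_pairs",
]

CLASSES = ("valid", "self_ligation", "re_ligation", "heterodimer")


@dataclass
class PairClassParams:
    short_range_max: int = 5_000
    dup_window: int = 2


@dataclass
class PairRecord:
    read_id: str
    tag_l: TagAlignment
    tag_r: TagAlignment
    frag_l: int = -1
    frag_r: int = -1
    linker_type: str = "AA"
    cls: str = ""
    duplicate: bool = False
    locality: str = ""  # intra | inter
    range: str = ""  # short | long | n/a

    @property
    def pos5_l(self) -> int:
        return five_prime_coordinate(self.tag_l.pos, self.tag_l.end, self.tag_l.strand)

    @property
    def pos5_r(self) -> int:
        return five_prime_coordinate(self.tag_r.pos, self.tag_r.end, self.tag_r.strand)


def join_pairs(
    left: Sequence[TagAlignment],
    right: Sequence[TagAlignment],
    linker_types: dict[str, str] | None = None,
) -> tuple[list[PairRecord], int]:
    """Join unique left/right alignments by read id.

    Returns (pairs, singleton count); a read id seen on only one side is a
    singleton.  Duplicated ids within one side are an input error.
    """
    sides = []
    for name, alns in (("left", left), ("right", right)):
        table: dict[str, TagAlignment] = {}
        for a in alns:
            if a.category != "unique":
                raise ValueError(f"{name} table contains non-unique alignment {a.read_id}")
            if a.read_id in table:
                raise ValueError(f"duplicate read_id {a.read_id!r} in {name} table")
            table[a.read_id] = a
        sides.append(table)
    lt, rt = sides
    shared = sorted(set(lt) & set(rt))
    singletons = (len(lt) - len(shared)) + (len(rt) - len(shared))
    pairs = [
        PairRecord(rid, lt[rid], rt[rid],
                   linker_type=(linker_types or {}).get(rid, "AA"))
        for rid in shared
    ]
    return pairs, singletons


def classify_pair(p: PairRecord, index: FragmentIndex,
                  params: PairClassParams | None = None) -> PairRecord:
    """Assign fragments, noise class, locality and range to a pair."""
    params = params or PairClassParams()
    frag_l = assign_fragment(index, p.tag_l.chrom, p.pos5_l)
    frag_r = assign_fragment(index, p.tag_r.chrom, p.pos5_r)
    intra = p.tag_l.chrom == p.tag_r.chrom
    if p.linker_type in ("AB", "BA"):
        cls = "heterodimer"
    elif intra and frag_l == frag_r:
        cls = "self_ligation"
    elif intra and abs(frag_l - frag_r) == 1:
        cls = "re_ligation"
    else:
        cls = "valid"
    if intra:
        rng = "short" if abs(p.pos5_l - p.pos5_r) <= params.short_range_max else "long"
    else:
        rng = "n/a"
    return replace(p, frag_l=frag_l, frag_r=frag_r, cls=cls,
                   locality="intra" if intra else "inter", range=rng)


def _sort_key(p: PairRecord):
    return (p.tag_l.chrom, p.pos5_l, p.tag_r.chrom, p.pos5_r,
            p.tag_l.strand, p.tag_r.strand, p.read_id)


def deduplicate(pairs: Sequence[PairRecord],
                params: PairClassParams | None = None) -> list[PairRecord]:
    """Flag PCR duplicates; the first pair (in sort order) of each
    single-linkage cluster is retained.

    Two pairs link when both chromosomes and both strands match and each
    end's 5' coordinates differ by at most ``dup_window``.  Chains such as
    positions 100/102/104 collapse into one cluster.  Input must be sorted
    by (chromL, posL, chromR, posR); the result depends only on that
    order, not on the caller's ordering history.
    """
    params = params or PairClassParams()
    w = params.dup_window
    keys = [_sort_key(p) for p in pairs]
    if keys != sorted(keys):
        raise ValueError("deduplicate requires pairs sorted by position")
    parent = list(range(len(pairs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i, p in enumerate(pairs):
        j = i - 1
        while j >= 0:
            q = pairs[j]
            if q.tag_l.chrom != p.tag_l.chrom or p.pos5_l - q.pos5_l > w:
                break
            if (
                q.tag_r.chrom == p.tag_r.chrom
                and q.tag_l.strand == p.tag_l.strand
                and q.tag_r.strand == p.tag_r.strand
                and abs(p.pos5_r - q.pos5_r) <= w
            ):
                union(i, j)
            j -= 1
    first: dict[int, int] = {}
    for i in range(len(pairs)):
        first.setdefault(find(i), i)
    return [replace(p, duplicate=(first[find(i)] != i)) for i, p in enumerate(pairs)]


def summarize_pairs(pairs: Iterable[PairRecord], singletons: int = 0) -> dict:
    """Counts per class, linker type, locality, range and duplicates."""
    by_class: Counter = Counter()
    by_linker: Counter = Counter()
    locality: Counter = Counter()
    rng: Counter = Counter()
    duplicates = 0
    total = 0
    for p in pairs:
        total += 1
        by_class[p.cls] += 1
        by_linker[p.linker_type] += 1
        if p.duplicate:
            duplicates += 1
        if p.cls == "valid" and not p.duplicate:
            locality[p.locality] += 1
            if p.locality == "intra":
                rng[p.range] += 1
    return {
        "pairs": total,
        "singletons": singletons,
        "classes": {c: by_class.get(c, 0) for c in CLASSES},
        "linker_types": dict(by_linker),
        "duplicates": duplicates,
        "valid_nondup": {
            "intra": locality.get("intra", 0),
            "inter": locality.get("inter", 0),
            "intra_short": rng.get("short", 0),
            "intra_long": rng.get("long", 0),
        },
    }


def write_pairs(path: str | Path, pairs: Iterable[PairRecord]) -> None:
    """Tab-separated pairs table (a superset of the community pairs format)."""
    with open(path, "w") as fh:
        fh.write("#readID\tchrom1\tpos1\tstrand1\tchrom2\tpos2\tstrand2"
                 "\tfragment1\tfragment2\tlinker_type\tclass\tduplicate\n")
        for p in pairs:
            fh.write(
                f"{p.read_id}\t{p.tag_l.chrom}\t{p.pos5_l}\t{p.tag_l.strand}"
                f"\t{p.tag_r.chrom}\t{p.pos5_r}\t{p.tag_r.strand}"
                f"\t{p.frag_l}\t{p.frag_r}\t{p.linker_type}\t{p.cls}"
                f"\t{int(p.duplicate)}\n"
            )
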