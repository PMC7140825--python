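"""Independent brute-force oracles used to check the fast implementations.

These deliberately share no code with the package: the local-alignment
oracle is a plain-Python dynamic program and the mapping oracle is a
direct Hamming scan of the genome.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def sw_oracle(read: str, query: str, match: int = 1, mismatch: int = -1,
              indel: int = -1) -> tuple[int, int, int]:
    """Smith-Waterman with linear gaps and deterministic tie-breaks.

    Within a cell, the move with the smallest alignment start wins ties;
    across cells, maximize score, then minimize start, then minimize end.
    Returns (score, start, end) with 0-based half-open read coordinates.
    """
    n, m = len(read), len(query)
    h_prev = [0] * (n + 1)
    s_prev = list(range(n + 1))
    best = (0, 0, 0)
    for i in range(1, m + 1):
        h_cur = [0] * (n + 1)
        s_cur = [0] * (n + 1)
        qi = query[i - 1]
        for j in range(1, n + 1):
            sub = match if read[j - 1] == qi else mismatch
            cands = [
                (h_prev[j - 1] + sub, s_prev[j - 1]),
                (h_prev[j] + indel, s_prev[j]),
                (h_cur[j - 1] + indel, s_cur[j - 1]),
            ]
            h = max(c[0] for c in cands)
            if h <= 0:
                h_cur[j], s_cur[j] = 0, j
                continue
            s = min(sc for c, sc in cands if c == h)
            h_cur[j], s_cur[j] = h, s
            score, start, end = best
            if h > score or (h == score and (s < start or (s == start and j < end))):
                best = (h, s, j)
        h_prev, s_prev = h_cur, s_cur
    return best


def mismatch_scan_oracle(genome: dict[str, str], tag: str,
                         max_mm: int) -> list[tuple[int, str, int, str]]:
    """All (mismatches, chrom, pos, strand) placements within max_mm."""
    hits = []
    for strand, q in (("+", tag), ("-", rc(tag))):
        for chrom, seq in genome.items():
            for pos in range(len(seq) - len(q) + 1):
                mm = sum(a != b for a, b in zip(seq[pos : pos + len(q)], q))
                if mm <= max_mm:
                    hits.append((mm, chrom, pos, strand))
    return hits
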