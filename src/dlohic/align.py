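"""Scored local alignment used for linker location.

This is a Smith-Waterman dynamic program with linear (per-base) gap
penalties, vectorized across reads: the DP loops run over the query and
read positions while every arithmetic step operates on a vector of reads
at once.  Alignment scores are match/mismatch/indel integers (defaults
+1/-1/-1) and the reported coordinates are the 0-based half-open span of
the alignment within the read.

Tie-breaking is deterministic and shared with the test oracles:

* within a DP cell, when several moves achieve the cell maximum, the move
  with the smallest alignment start is kept;
* across cells, the best cell maximizes score, then minimizes start, then
  minimizes end.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ._seq import encode

__all__ = ["local_align", "local_align_batch"]


def _align_group(mat: np.ndarray, query: np.ndarray, match: int, mismatch: int,
                 indel: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DP over one group of equal-length reads.

    mat: (N, L) uint8 codes; query: (m,) uint8 codes.
    Returns (score, start, end) arrays of length N.
    """
    n_reads, read_len = mat.shape
    m = len(query)
    big = np.iinfo(np.int32).max

    h_prev = np.zeros((n_reads, read_len + 1), dtype=np.int32)
    s_prev = np.broadcast_to(
        np.arange(read_len + 1, dtype=np.int32), (n_reads, read_len + 1)
    ).copy()
    h_cur = np.zeros_like(h_prev)
    s_cur = np.zeros_like(s_prev)

    best_score = np.zeros(n_reads, dtype=np.int32)
    best_start = np.zeros(n_reads, dtype=np.int32)
    best_end = np.zeros(n_reads, dtype=np.int32)

    for i in range(1, m + 1):
        h_cur[:, 0] = 0
        s_cur[:, 0] = 0
        qi = query[i - 1]
        for j in range(1, read_len + 1):
            sub = np.where(mat[:, j - 1] == qi, match, mismatch)
            diag = h_prev[:, j - 1] + sub
            up = h_prev[:, j] + indel
            left = h_cur[:, j - 1] + indel
            best = np.maximum(np.maximum(diag, up), left)
            start = np.full(n_reads, big, dtype=np.int32)
            for cand, s_cand in (
                (diag, s_prev[:, j - 1]),
                (up, s_prev[:, j]),
                (left, s_cur[:, j - 1]),
            ):
                start = np.where(cand == best, np.minimum(start, s_cand), start)
            pos = best > 0
            h_cur[:, j] = np.where(pos, best, 0)
            s_cur[:, j] = np.where(pos, start, j)

            h = h_cur[:, j]
            s = s_cur[:, j]
            upd = (h > best_score) | (
                (h == best_score)
                & ((s < best_start) | ((s == best_start) & (j < best_end)))
            )
            # score 0 never updates: best_score starts at 0 with start=end=0
            upd &= h > 0
            best_score = np.where(upd, h, best_score)
            best_start = np.where(upd, s, best_start)
            best_end = np.where(upd, j, best_end)
        h_prev, h_cur = h_cur, h_prev
        s_prev, s_cur = s_cur, s_prev

    return best_score, best_start, best_end


def local_align_batch(reads: Sequence[str], query: str, match: int = 1,
                      mismatch: int = -1, indel: int = -1) -> np.ndarray:
    """Best local alignment of ``query`` within each read.

    Returns an (N, 3) int array of (score, start, end); reads with no
    positive-scoring alignment get (0, 0, 0).
    """
    if not query:
        raise ValueError("empty query sequence")
    out = np.zeros((len(reads), 3), dtype=np.int64)
    q = encode(query)
    lengths = np.fromiter((len(r) for r in reads), dtype=np.int64, count=len(reads))
    for length in np.unique(lengths):
        idx = np.nonzero(lengths == length)[0]
        if length == 0:
            continue
        mat = np.empty((len(idx), length), dtype=np.uint8)
        for row, k in enumerate(idx):
            mat[row] = encode(reads[k])
        score, start, end = _align_group(mat, q, match, mismatch, indel)
        out[idx, 0] = score
        out[idx, 1] = start
        out[idx, 2] = end
    return out


def local_align(read: str, query: str, match: int = 1, mismatch: int = -1,
                indel: int = -1) -> tuple[int, int, int]:
    """Scalar convenience wrapper; identical tie-breaks to the batch path."""
    score, start, end = local_align_batch([read], query, match, mismatch, indel)[0]
    return int(score), int(start), int(end)
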