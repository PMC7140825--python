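"""Contact matrices: binning, O/E normalization, similarity measures.

Valid (non-duplicate, homodimer-linker) pairs are aggregated into
per-chromosome-pair matrices at a chosen resolution (bin size in bp).
Intra-chromosomal matrices are symmetric and stored upper-triangular.

The O/E (observed over expected) transform divides each intra cell by the
mean count at its bin distance, where the mean runs over the full diagonal
including empty cells — this removes the genomic distance decay.  Matrices
are compared by flattening to vectors (symmetrized, row-major) and taking
cosine similarity or Pearson's correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .pairs import PairRecord

__all__ = [
    "MatrixSpec",
    "ContactMatrix",
    "bin_pairs",
    "oe_normalize",
    "matrix_to_vector",
    "cosine_similarity",
    "pearson_correlation",
    "coarsen",
    "genome_vector",
]


@dataclass(frozen=True)
class MatrixSpec:
    resolution: int
    chrom_sizes: dict[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_sizes[chrom] / self.resolution)


@dataclass
class ContactMatrix:
    chrom1: str
    chrom2: str
    spec: MatrixSpec
    counts: dict[tuple[int, int], float] = field(default_factory=dict)
    transform: str = "raw"  # raw | OE

    @property
    def intra(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.spec.n_bins(self.chrom1), self.spec.n_bins(self.chrom2))

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def add(self, i: int, j: int, weight: float = 1.0) -> None:
        if self.intra and j < i:
            i, j = j, i
        self.counts[(i, j)] = self.counts.get((i, j), 0.0) + weight

    def dense(self, symmetrize: bool = True) -> np.ndarray:
        """Dense array; intra matrices are mirrored below the diagonal."""
        out = np.zeros(self.shape)
        for (i, j), v in self.counts.items():
            out[i, j] = v
            if self.intra and symmetrize and i != j:
                out[j, i] = v
        return out

    def to_coo(self) -> sparse.coo_matrix:
        if not self.counts:
            return sparse.coo_matrix(self.shape)
        ij = np.array(list(self.counts.keys()), dtype=np.int64)
        v = np.fromiter(self.counts.values(), dtype=float, count=len(self.counts))
        return sparse.coo_matrix((v, (ij[:, 0], ij[:, 1])), shape=self.shape)

    def write_triplets(self, path: str | Path) -> None:
        """Sparse triplet text: bin_i <TAB> bin_j <TAB> count."""
        with open(path, "w") as fh:
            for (i, j) in sorted(self.counts):
                v = self.counts[(i, j)]
                fh.write(f"{i}\t{j}\t{v:g}\n")


def bin_pairs(pairs: Iterable[PairRecord], spec: MatrixSpec,
              include_heterodimer: bool = False) -> dict[tuple[str, str], ContactMatrix]:
    """Aggregate valid, deduplicated pairs into per-chromosome-pair matrices.

    Each pair increments exactly one cell (pos // resolution on each end);
    the chromosome pair key is ordered lexicographically and intra cells
    are canonicalized to the upper triangle, so total counts are conserved.
    Heterodimer (AB/BA) pairs are excluded unless requested.
    """
    matrices: dict[tuple[str, str], ContactMatrix] = {}
    for p in pairs:
        if p.duplicate or p.cls != "valid":
            continue
        if not include_heterodimer and p.linker_type in ("AB", "BA"):
            continue
        c1, pos1 = p.tag_l.chrom, p.pos5_l
        c2, pos2 = p.tag_r.chrom, p.pos5_r
        if c2 < c1:
            c1, c2, pos1, pos2 = c2, c1, pos2, pos1
        for chrom, pos in ((c1, pos1), (c2, pos2)):
            if pos >= spec.chrom_sizes[chrom]:
                raise ValueError(f"position {chrom}:{pos} beyond chromosome end")
        key = (c1, c2)
        if key not in matrices:
            matrices[key] = ContactMatrix(c1, c2, spec)
        matrices[key].add(pos1 // spec.resolution, pos2 // spec.resolution)
    return matrices


def oe_normalize(m: ContactMatrix) -> ContactMatrix:
    """Observed/expected transform of an intra-chromosomal raw matrix.

    expected(d) averages the observed counts over every cell of diagonal
    d (length n - d, zero cells included); OE = obs / expected where
    expected > 0, else 0.  Each diagonal of the result with positive
    expected has mean exactly 1.
    """
    if not m.intra:
        raise ValueError("O/E is defined for intra-chromosomal matrices only")
    if m.transform != "raw":
        raise ValueError("O/E input must be a raw matrix")
    n = m.shape[0]
    diag_sum = np.zeros(n)
    for (i, j), v in m.counts.items():
        diag_sum[j - i] += v
    diag_len = n - np.arange(n)
    expected = np.divide(diag_sum, diag_len, out=np.zeros(n), where=diag_len > 0)
    oe = ContactMatrix(m.chrom1, m.chrom2, m.spec, transform="OE")
    for (i, j), v in m.counts.items():
        e = expected[j - i]
        oe.counts[(i, j)] = v / e if e > 0 else 0.0
    return oe


def matrix_to_vector(m: ContactMatrix) -> np.ndarray:
    """Row-major flattening of the dense (symmetrized) matrix."""
    return m.dense().ravel()


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    ac, bc = a - a.mean(), b - b.mean()
    return float(np.dot(ac, bc) / (np.linalg.norm(ac) * np.linalg.norm(bc)))


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Aggregate bins k-fold; equals direct binning at k x resolution."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    spec = MatrixSpec(m.spec.resolution * factor, m.spec.chrom_sizes)
    out = ContactMatrix(m.chrom1, m.chrom2, spec, transform=m.transform)
    for (i, j), v in m.counts.items():
        out.add(i // factor, j // factor, v)
    return out


def genome_vector(matrices: dict[tuple[str, str], ContactMatrix]) -> np.ndarray:
    """Whole-genome vector: per-chromosome-pair vectors concatenated in
    lexicographic chromosome-pair order."""
    parts = [matrix_to_vector(matrices[key]) for key in sorted(matrices)]
    if not parts:
        return np.zeros(0)
    return np.concatenate(parts)
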