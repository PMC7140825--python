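"""Small sequence utilities shared across the pipeline."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: 2-bit encoding used by the batched aligners. Non-ACGT maps to 4 (invalid).
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes A=0 C=1 G=2 T=3, other=4."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def is_nucleotide(seq: str) -> bool:
    return len(seq) > 0 and all(c in "ACGT" for c in seq)


@dataclass
class FastqRecord:
    """One FASTQ read (sequence and quality must be equal length)."""

    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.read_id}: sequence/quality length mismatch"
            )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream records from a FASTQ or gzip-compressed FASTQ file."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record near {header!r}")
            yield FastqRecord(header[1:].split()[0].rstrip("\n"), seq, qual)


def write_fastq(path: str | Path, records: Iterable[FastqRecord]) -> int:
    """Write FASTQ (gzip-compressed when the path ends in .gz). Returns count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.seq}\n+\n{rec.qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (plain or gzip) FASTA file into an ordered name->sequence dict."""
    seqs: dict[str, list[str]] = {}
    name = None
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None and line:
                seqs[name].append(line)
    return {k: "".join(v).upper() for k, v in seqs.items()}


def write_fasta(path: str | Path, seqs: dict[str, str], width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
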