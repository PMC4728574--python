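"""Internal sequence-file plumbing shared by the pipeline modules.

Thin wrappers around Biopython readers plus a few sequence utilities.
Reads and writes only plain-text formats (FASTA, Phred+33 FASTQ, TSV).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "revcomp",
    "package_data_path",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC beyond ACGTN not supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict.

    Raises ``ValueError`` on duplicate ids or empty sequences; downstream
    coverage arithmetic divides by sequence length, so zero-length records
    are rejected here.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"zero-length sequence {rec.id!r} in {path}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """Read Phred+33 FASTQ into a list of (id, sequence, quality) tuples."""
    with open(path) as fh:
        return [(title.split()[0], seq, qual) for title, seq, qual in FastqGeneralIterator(fh)]


def write_fastq(reads: Iterable[Sequence[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def package_data_path(filename: str) -> str:
    """Absolute path of a file shipped under ``viromenet/data``."""
    return os.path.join(os.path.dirname(__file__), "data", filename)
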