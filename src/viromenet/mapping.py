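"""Read QC and strict full-length zero-mismatch read placement.

The mapping contract is deliberately austere: a read is mapped iff its
sequence (or reverse complement) occurs as an exact substring of some
contig, i.e. it aligns over its entire length with no mismatches. Both
"sensitive paired" and "fast unpaired" aligner presets collapse to this
same contract — preset differences affect search effort, not the match
criterion — so the matcher is a substring index, not a scoring aligner:
no gaps, no soft clips, no mapping qualities.

Multi-mapping tie-break (deterministic, so results are independent of
read and contig order): the placement on the lexicographically smallest
contig_id, then the smallest start, then '+' before '-'. Exactly one
placement is reported per read; mates are placed independently with no
insert-size constraint.

QC mirrors sliding-window 3' trimming: a read is cut at the first window
whose mean quality drops below the threshold, then dropped if its mean
quality or length is too low; in paired mode a pair is dropped as a unit
when either mate is dropped.

Coverage is mean depth: total mapped bases on a contig divided by contig
length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from .fileio import revcomp

__all__ = [
    "AlignmentRecord",
    "MappingResult",
    "ExactMatcher",
    "FastqFormatError",
    "SamReferenceError",
    "trim_point",
    "qc_reads",
    "map_reads_exact",
    "read_sam",
    "compute_coverage",
    "mapped_fraction",
    "screen_contaminants",
    "export_mapping",
    "read_mapping",
]

logger = logging.getLogger(__name__)


class FastqFormatError(ValueError):
    """Malformed FASTQ input (mate-count mismatch, non-Phred33 qualities)."""


class SamReferenceError(ValueError):
    """SAM header sequences do not match the supplied contigs."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One full-length zero-mismatch placement of a mate on a contig."""

    pair_id: str
    mate: int  # 1 or 2; 0 in unpaired mode
    contig_id: str
    start: int  # 0-based position on the contig
    strand: str  # '+' or '-'
    read_length: int


@dataclass
class MappingResult:
    records: list[AlignmentRecord]
    n_reads_total: int
    n_reads_mapped: int
    mode: str  # "paired" | "unpaired"

    def __post_init__(self) -> None:
        if self.n_reads_mapped > self.n_reads_total:
            raise ValueError("n_reads_mapped exceeds n_reads_total")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

_PHRED33_MAX = 33 + 42  # anything above 'K' is treated as non-Phred33


def _check_phred33(qual: str) -> None:
    for c in qual:
        o = ord(c)
        if o < 33 or o > _PHRED33_MAX:
            raise FastqFormatError(f"quality character {c!r} outside Phred+33 range")


def trim_point(qual: str, min_quality: int = 25, window: int = 4) -> int:
    """Length to keep: position of the first sliding window whose mean
    quality falls below ``min_quality`` (whole read if none does)."""
    n = len(qual)
    # fast path: no base below threshold means no window can fail
    if n and min(qual) >= chr(33 + min_quality):
        return n
    q = [ord(c) - 33 for c in qual]
    for i in range(n - window + 1):
        if sum(q[i : i + window]) / window < min_quality:
            return i
    return n


def _qc_one(read: Sequence[str], min_quality: int, min_length: int, window: int,
            per_base: bool) -> tuple[str, str, str] | None:
    name, seq, qual = read
    _check_phred33(qual)
    keep = trim_point(qual, min_quality, window)
    seq, qual = seq[:keep], qual[:keep]
    if keep < min_length:
        return None
    q = [ord(c) - 33 for c in qual]
    ok = min(q) >= min_quality if per_base else sum(q) / len(q) >= min_quality
    return (name, seq, qual) if ok else None


def qc_reads(
    reads1: Sequence[Sequence[str]],
    reads2: Sequence[Sequence[str]] | None = None,
    min_quality: int = 25,
    min_length: int = 150,
    window: int = 4,
    per_base: bool = False,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], dict]:
    """Sliding-window 3' trimming plus quality/length filtering.

    ``per_base=False`` (default) applies the quality floor to the mean
    post-trim quality; ``per_base=True`` requires every base to pass. In
    paired mode (``reads2`` given) a pair is dropped as a unit if either
    mate fails. Returns (kept_1, kept_2, report).
    """
    paired = reads2 is not None
    if paired and len(reads1) != len(reads2):
        raise FastqFormatError(
            f"mate files differ in record count: {len(reads1)} vs {len(reads2)}"
        )
    kept1: list[tuple[str, str, str]] = []
    kept2: list[tuple[str, str, str]] = []
    n_dropped = 0
    if paired:
        for r1, r2 in zip(reads1, reads2):
            a = _qc_one(r1, min_quality, min_length, window, per_base)
            b = _qc_one(r2, min_quality, min_length, window, per_base)
            if a is None or b is None:
                n_dropped += 1
            else:
                kept1.append(a)
                kept2.append(b)
        report = {
            "mode": "paired",
            "n_pairs_in": len(reads1),
            "n_pairs_kept": len(kept1),
            "n_pairs_dropped": n_dropped,
            "min_quality": min_quality,
            "min_length": min_length,
            "window": window,
        }
        return kept1, kept2, report
    for r in reads1:
        a = _qc_one(r, min_quality, min_length, window, per_base)
        if a is None:
            n_dropped += 1
        else:
            kept1.append(a)
    report = {
        "mode": "unpaired",
        "n_reads_in": len(reads1),
        "n_reads_kept": len(kept1),
        "n_reads_dropped": n_dropped,
        "min_quality": min_quality,
        "min_length": min_length,
        "window": window,
    }
    return kept1, [], report


# ---------------------------------------------------------------------------
# exact substring matcher
# ---------------------------------------------------------------------------

class ExactMatcher:
    """K-mer anchored exact substring search over a contig set.

    Indexes every k-mer of every contig; a query is anchored by its first
    k bases (or the reverse complement's) and verified by direct string
    comparison, so reported placements are exact full-length matches.
    Queries shorter than k fall back to a linear scan.
    """

    def __init__(self, contigs: Mapping[str, str], k: int = 31):
        if not contigs:
            raise ValueError("contigs must be non-empty")
        self.k = k
        self.contigs = dict(sorted(contigs.items()))
        index: dict[str, list[tuple[str, int]]] = {}
        for cid, seq in self.contigs.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((cid, i))
        self._index = index

    def _scan(self, query: str) -> list[tuple[str, int]]:
        out = []
        for cid, seq in self.contigs.items():
            pos = seq.find(query)
            while pos != -1:
                out.append((cid, pos))
                pos = seq.find(query, pos + 1)
        return out

    def _anchored(self, query: str) -> list[tuple[str, int]]:
        if len(query) < self.k:
            return self._scan(query)
        hits = []
        for cid, pos in self._index.get(query[: self.k], ()):  # verified below
            if self.contigs[cid][pos : pos + len(query)] == query:
                hits.append((cid, pos))
        return hits

    def placements(self, query: str) -> list[tuple[str, int, str]]:
        """All exact full-length placements as (contig_id, start, strand)."""
        fwd = [(cid, pos, "+") for cid, pos in self._anchored(query)]
        rev = [(cid, pos, "-") for cid, pos in self._anchored(revcomp(query))]
        return sorted(fwd + rev, key=lambda p: (p[0], p[1], p[2] != "+"))

    def best(self, query: str) -> tuple[str, int, str] | None:
        """The tie-broken single placement, or None if unmapped."""
        hits = self.placements(query)
        return hits[0] if hits else None


def _iter_mates(reads, mode: str):
    if mode == "paired":
        reads1, reads2 = reads
        for r in reads1:
            yield r[0], 1, r[1]
        for r in reads2:
            yield r[0], 2, r[1]
    else:
        for r in reads:
            yield r[0], 0, r[1]


def map_reads_exact(
    reads,
    contigs: Mapping[str, str] | ExactMatcher,
    mode: str = "unpaired",
    k: int = 31,
) -> MappingResult:
    """Place reads on contigs under the full-length zero-mismatch contract.

    ``reads`` is a list of (id, seq[, qual]) tuples in unpaired mode, or a
    (mates_1, mates_2) tuple of such lists in paired mode. A pre-built
    :class:`ExactMatcher` may be passed to amortize indexing.
    """
    if mode not in ("paired", "unpaired"):
        raise ValueError(f"unknown mode {mode!r}")
    matcher = contigs if isinstance(contigs, ExactMatcher) else ExactMatcher(contigs, k=k)
    records: list[AlignmentRecord] = []
    total = 0
    for name, mate, seq in _iter_mates(reads, mode):
        total += 1
        hit = matcher.best(seq)
        if hit is not None:
            cid, start, strand = hit
            pair_id = name[:-2] if mate and name.endswith(f"/{mate}") else name
            records.append(AlignmentRecord(pair_id, mate, cid, start, strand, len(seq)))
    if total == 0:
        warnings.warn("empty read input: returning empty mapping result", stacklevel=2)
    return MappingResult(records, total, len(records), mode)


# ---------------------------------------------------------------------------
# SAM import
# ---------------------------------------------------------------------------

def read_sam(path: str, contigs: Mapping[str, str]) -> MappingResult:
    """Import externally produced alignments, keeping only records that
    honor the contract: mapped, CIGAR entirely match operations spanning
    the whole read, and NM tag 0 (records lacking NM are accepted only
    when the CIGAR uses '=' exclusively, else skipped with a warning).

    SAM 1-based coordinates are converted to internal 0-based starts.
    Secondary and supplementary records are ignored entirely.
    """
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        names = list(sam.header.references)
        lengths = list(sam.header.lengths)
        header = dict(zip(names, lengths))
        expected = {cid: len(seq) for cid, seq in contigs.items()}
        if header != expected:
            raise SamReferenceError(
                "SAM @SQ header does not match contigs "
                f"(header {len(header)} seqs, contigs {len(expected)})"
            )
        records: list[AlignmentRecord] = []
        total = 0
        for aln in sam.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary:
                continue
            total += 1
            if aln.is_unmapped:
                continue
            cig = aln.cigartuples or []
            # full length, match ops only (M=0, '='=7); soft/hard clips fail
            if not cig or any(op not in (0, 7) for op, _ in cig):
                continue
            if sum(n for _, n in cig) != len(aln.query_sequence or ""):
                continue
            if aln.has_tag("NM"):
                if aln.get_tag("NM") != 0:
                    continue
            elif not all(op == 7 for op, _ in cig):
                logger.warning(
                    "SAM record %s lacks NM tag and CIGAR is not '='-only; skipped",
                    aln.query_name,
                )
                continue
            mate = 1 if aln.is_read1 else 2 if aln.is_read2 else 0
            records.append(
                AlignmentRecord(
                    aln.query_name,
                    mate,
                    aln.reference_name,
                    aln.reference_start,
                    "-" if aln.is_reverse else "+",
                    len(aln.query_sequence or ""),
                )
            )
    mode = "paired" if any(r.mate for r in records) else "unpaired"
    return MappingResult(records, total, len(records), mode)


# ---------------------------------------------------------------------------
# coverage and fractions
# ---------------------------------------------------------------------------

def compute_coverage(result: MappingResult, contigs: Mapping[str, str]) -> dict[str, float]:
    """Mean fold coverage per contig: mapped bases / contig length.

    Contigs without records get 0.0; a record on a contig absent from
    ``contigs`` is an error.
    """
    bases: dict[str, int] = {cid: 0 for cid in contigs}
    for rec in result.records:
        if rec.contig_id not in bases:
            raise ValueError(f"record references unknown contig {rec.contig_id!r}")
        bases[rec.contig_id] += rec.read_length
    return {cid: bases[cid] / len(seq) for cid, seq in contigs.items()}


def mapped_fraction(result: MappingResult) -> float:
    if result.n_reads_total == 0:
        raise ValueError("mapped_fraction undefined for zero reads")
    return result.n_reads_mapped / result.n_reads_total


def screen_contaminants(
    reads1: Sequence[Sequence[str]],
    reads2: Sequence[Sequence[str]] | None,
    contaminant: Mapping[str, str],
    k: int = 31,
) -> tuple[list, list, int]:
    """Drop read pairs (or single reads) that map to a contaminant
    reference under the exact contract. Returns (kept_1, kept_2, n_removed
    pairs/reads)."""
    matcher = ExactMatcher(contaminant, k=k)
    kept1, kept2 = [], []
    removed = 0
    if reads2 is not None:
        for r1, r2 in zip(reads1, reads2):
            if matcher.best(r1[1]) is None and matcher.best(r2[1]) is None:
                kept1.append(tuple(r1))
                kept2.append(tuple(r2))
            else:
                removed += 1
        return kept1, kept2, removed
    for r in reads1:
        if matcher.best(r[1]) is None:
            kept1.append(tuple(r))
        else:
            removed += 1
    return kept1, [], removed


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def export_mapping(result: MappingResult, path: str) -> None:
    """Write a MappingResult as TSV with counts in comment headers."""
    with open(path, "w") as fh:
        fh.write(f"# mode={result.mode}\n")
        fh.write(f"# n_reads_total={result.n_reads_total}\n")
        fh.write(f"# n_reads_mapped={result.n_reads_mapped}\n")
        fh.write("pair_id\tmate\tcontig_id\tstart0\tstrand\tlength\n")
        for r in result.records:
            fh.write(f"{r.pair_id}\t{r.mate}\t{r.contig_id}\t{r.start}\t{r.strand}\t{r.read_length}\n")


def read_mapping(path: str) -> MappingResult:
    meta: dict[str, str] = {}
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition("=")
                meta[key] = val
                continue
            if not header_seen:
                header_seen = True  # column header row
                continue
            if not line:
                continue
            pid, mate, cid, start, strand, length = line.split("\t")
            records.append(AlignmentRecord(pid, int(mate), cid, int(start), strand, int(length)))
    return MappingResult(
        records,
        int(meta.get("n_reads_total", len(records))),
        int(meta.get("n_reads_mapped", len(records))),
        meta.get("mode", "unpaired"),
    )
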