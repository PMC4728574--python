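"""QC trimming, exact full-length zero-mismatch placement, SAM import,
coverage, and mapped fractions."""

import numpy as np
import pytest

from viromenet.fileio import revcomp
from viromenet.mapping import (
    ExactMatcher,
    FastqFormatError,
    SamReferenceError,
    compute_coverage,
    map_reads_exact,
    mapped_fraction,
    qc_reads,
    read_mapping,
    export_mapping,
    read_sam,
    screen_contaminants,
    trim_point,
)


def _qual(values):
    return "".join(chr(33 + v) for v in values)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_high_quality_read_is_unchanged():
    read = ("r1", "A" * 200, "I" * 200)  # Q40 throughout
    kept, _, report = qc_reads([read])
    assert kept == [read]
    assert report["n_reads_dropped"] == 0


def test_read_trimmed_below_min_length_is_dropped():
    # 160 good bases then a low-quality tail: trimmed to 140 < 150 -> dropped
    qual = _qual([40] * 140 + [2] * 60)
    kept, _, report = qc_reads([("r1", "A" * 200, qual)])
    assert kept == []
    assert report["n_reads_dropped"] == 1


def test_pair_dropped_as_unit_when_one_mate_fails():
    good = ("p/1", "A" * 200, "I" * 200)
    bad = ("p/2", "A" * 200, _qual([2] * 200))
    k1, k2, report = qc_reads([good], [bad])
    assert k1 == [] and k2 == []
    assert report["n_pairs_dropped"] == 1


def test_mate_count_mismatch_is_format_error():
    r = ("a", "ACGT", "IIII")
    with pytest.raises(FastqFormatError):
        qc_reads([r, r], [r])


def test_non_phred33_quality_rejected():
    with pytest.raises(FastqFormatError):
        qc_reads([("r", "ACGT", "h\x7fII")])


def _brute_trim(qual, minq, window):
    q = [ord(c) - 33 for c in qual]
    for i in range(len(q) - window + 1):
        if sum(q[i : i + window]) / window < minq:
            return i
    return len(q)


def test_trim_points_match_exhaustive_window_scan(rng):
    """Oracle: evaluate every window position explicitly on 1,000 random
    decaying-tail reads."""
    for _ in range(1000):
        n = int(rng.integers(30, 200))
        start = int(rng.integers(0, n))
        q = [40] * start + list(
            np.maximum(40 - rng.integers(0, 6, n - start).cumsum(), 0)
        )
        qual = _qual([int(v) for v in q])
        assert trim_point(qual, 25, 4) == _brute_trim(qual, 25, 4)


# ---------------------------------------------------------------------------
# exact mapping
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def contig_set():
    rng = np.random.default_rng(21)
    return {
        "c1": "".join(rng.choice(list("ACGT"), 600)),
        "c2": "".join(rng.choice(list("ACGT"), 400)),
    }


def test_forward_placement(contig_set):
    read = contig_set["c1"][100:274]
    res = map_reads_exact([("r", read)], contig_set)
    (rec,) = res.records
    assert (rec.contig_id, rec.start, rec.strand) == ("c1", 100, "+")


def test_reverse_complement_placement(contig_set):
    read = revcomp(contig_set["c1"][0:174])
    res = map_reads_exact([("r", read)], contig_set)
    (rec,) = res.records
    assert (rec.contig_id, rec.start, rec.strand) == ("c1", 0, "-")


def test_single_mismatch_is_unmapped(contig_set):
    read = list(contig_set["c1"][100:274])
    read[50] = {"A": "C"}.get(read[50], "A")
    res = map_reads_exact([("r", "".join(read))], contig_set)
    assert res.records == [] and res.n_reads_mapped == 0


def test_multimapper_tiebreak_smallest_contig_then_start():
    common = "ACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 36 bp, present in both
    contigs = {"b": "TT" + common + "AA" + common, "a": "GGGG" + common}
    res = map_reads_exact([("r", common)], contigs, k=8)
    (rec,) = res.records
    assert (rec.contig_id, rec.start) == ("a", 4)
    # within one contig, the smallest start wins
    res2 = map_reads_exact([("r", common)], {"b": contigs["b"]}, k=8)
    assert res2.records[0].start == 2


def test_plus_strand_preferred_on_equal_position():
    pal = "AATT"  # its own reverse complement
    res = map_reads_exact([("r", pal)], {"c": "GG" + pal + "CC"}, k=2)
    assert res.records[0].strand == "+"


def test_mapping_independent_of_read_and_contig_order(contig_set):
    reads = [("r1", contig_set["c1"][5:179]), ("r2", contig_set["c2"][10:184])]
    res_a = map_reads_exact(reads, contig_set)
    res_b = map_reads_exact(reads[::-1], dict(reversed(contig_set.items())))
    assert sorted(map(str, res_a.records)) == sorted(map(str, res_b.records))


def test_empty_reads_warn_and_return_empty(contig_set):
    with pytest.warns(UserWarning):
        res = map_reads_exact([], contig_set)
    assert res.n_reads_total == 0 and res.records == []


def test_short_query_fallback_scan(contig_set):
    read = contig_set["c2"][17:37]  # 20 bp < default k
    res = map_reads_exact([("r", read)], contig_set)
    assert res.records[0].contig_id == "c2"
    assert res.records[0].start == contig_set["c2"].find(read)


# ---------------------------------------------------------------------------
# SAM import
# ---------------------------------------------------------------------------

def _write_sam(path, contigs, lines):
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid, seq in contigs.items():
            fh.write(f"@SQ\tSN:{cid}\tLN:{len(seq)}\n")
        fh.writelines(lines)


def test_read_sam_contract(tmp_path, contig_set):
    seq174 = contig_set["c1"][100:274]
    lines = [
        # kept: full-length match, NM 0, POS 101 -> start 100
        f"q1\t0\tc1\t101\t42\t174M\t*\t0\t0\t{seq174}\t{'I' * 174}\tNM:i:0\n",
        # excluded: soft clip (not full length)
        f"q2\t0\tc1\t101\t42\t170M4S\t*\t0\t0\t{seq174}\t{'I' * 174}\tNM:i:0\n",
        # excluded: one mismatch
        f"q3\t0\tc1\t101\t42\t174M\t*\t0\t0\t{seq174}\t{'I' * 174}\tNM:i:1\n",
        # excluded but counted: unmapped flag
        f"q4\t4\t*\t0\t0\t*\t*\t0\t0\t{seq174}\t{'I' * 174}\n",
        # kept: '='-only CIGAR without NM tag
        f"q5\t16\tc1\t101\t42\t174=\t*\t0\t0\t{seq174}\t{'I' * 174}\n",
    ]
    path = tmp_path / "aln.sam"
    _write_sam(path, contig_set, lines)
    res = read_sam(str(path), contig_set)
    assert res.n_reads_total == 5
    assert {r.pair_id for r in res.records} == {"q1", "q5"}
    rec = next(r for r in res.records if r.pair_id == "q1")
    assert rec.start == 100 and rec.strand == "+"
    rec5 = next(r for r in res.records if r.pair_id == "q5")
    assert rec5.strand == "-"


def test_read_sam_header_mismatch(tmp_path, contig_set):
    path = tmp_path / "bad.sam"
    _write_sam(path, {"other": "ACGT" * 50}, [])
    with pytest.raises(SamReferenceError):
        read_sam(str(path), contig_set)


# ---------------------------------------------------------------------------
# coverage and fractions
# ---------------------------------------------------------------------------

def test_coverage_arithmetic():
    # 10 mapped reads of 50 bases on a 100-base contig -> 5.0x
    contig = {"c": "".join("ACGT"[i % 4] for i in range(100))}
    reads = [(f"r{i}", contig["c"][0:50]) for i in range(10)]
    res = map_reads_exact(reads, contig, k=8)
    cov = compute_coverage(res, contig)
    assert cov["c"] == pytest.approx(5.0)


def test_coverage_of_contig_without_records(contig_set):
    res = map_reads_exact([("r", contig_set["c1"][0:174])], contig_set)
    cov = compute_coverage(res, contig_set)
    assert cov["c2"] == 0.0


def test_coverage_equals_mean_pileup_depth(rng):
    """Oracle: explicit per-base depth array over 500 random placements."""
    from viromenet.mapping import AlignmentRecord, MappingResult

    contigs = {f"c{i}": "A" * int(rng.integers(300, 900)) for i in range(5)}
    records = []
    depth = {cid: np.zeros(len(s)) for cid, s in contigs.items()}
    for i in range(500):
        cid = f"c{rng.integers(0, 5)}"
        L = len(contigs[cid])
        rl = int(rng.integers(30, 120))
        start = int(rng.integers(0, L - rl + 1))
        records.append(AlignmentRecord(f"r{i}", 0, cid, start, "+", rl))
        depth[cid][start : start + rl] += 1
    res = MappingResult(records, 500, 500, "unpaired")
    cov = compute_coverage(res, contigs)
    for cid in contigs:
        assert cov[cid] == pytest.approx(depth[cid].mean())
    # conservation: sum of coverage x length equals total mapped bases
    total = sum(cov[c] * len(s) for c, s in contigs.items())
    assert total == pytest.approx(sum(r.read_length for r in records))


def test_mapped_fraction_cases(contig_set):
    reads = [("r1", contig_set["c1"][0:174]), ("r2", contig_set["c1"][1:175]),
             ("r3", contig_set["c2"][0:174]), ("r4", "A" * 174)]
    res = map_reads_exact(reads, contig_set)
    assert mapped_fraction(res) == 0.75
    from viromenet.mapping import MappingResult

    with pytest.raises(ValueError):
        mapped_fraction(MappingResult([], 0, 0, "unpaired"))


def test_screen_contaminants_drops_pairs(contig_set):
    contaminant = {"phix": contig_set["c2"]}
    pairs1 = [("p1/1", contig_set["c1"][0:100], "I" * 100),
              ("p2/1", contig_set["c2"][0:100], "I" * 100)]
    pairs2 = [("p1/2", contig_set["c1"][100:200], "I" * 100),
              ("p2/2", contig_set["c1"][200:300], "I" * 100)]
    k1, k2, removed = screen_contaminants(pairs1, pairs2, contaminant)
    assert removed == 1
    assert [r[0] for r in k1] == ["p1/1"]


def test_mapping_tsv_roundtrip(tmp_path, contig_set):
    reads = ([("p/1", contig_set["c1"][0:174], "I" * 174)],
             [("p/2", revcomp(contig_set["c1"][200:374]), "I" * 174)])
    res = map_reads_exact(reads, contig_set, mode="paired")
    path = tmp_path / "map.tsv"
    export_mapping(res, str(path))
    back = read_mapping(str(path))
    assert back.mode == "paired"
    assert back.n_reads_total == res.n_reads_total
    assert back.records == res.records
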