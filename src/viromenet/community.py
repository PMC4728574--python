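"""Ground-truthed synthetic viral community generator.

Emulates the data structure of an MDA-amplified salt-pan metavirome:

* a mix of small circular ssDNA genomes (Microviridae / Circoviridae scale,
  4-7 kb) and larger linear dsDNA genomes (tailed-phage scale, 30-60 kb);
* highly uneven lognormal relative abundances;
* a multiplicative MDA amplification weight applied to circular ssDNA
  genomes only, modelling the preferential phi29 amplification of circular
  ssDNA templates as a single per-genome factor (not a branching-process
  simulation) — its magnitude is a free parameter, default 10;
* fragmentation of every genome into contigs that tile it exactly, standing
  in for short-read assembly: a linear genome with breakpoints b1<...<bk
  yields k+1 contigs; a circular genome is linearized by its first
  breakpoint, so one breakpoint gives a single full-length rotated contig;
* paired-end reads drawn with probability proportional to
  abundance x mda_factor x length, fragment length normal(insert_mean,
  insert_sd) truncated to [read_length, genome length], fragment start
  uniform (wrapping the origin on circular genomes), second mate
  reverse-complemented, optional i.i.d. substitution errors, and an
  optional contaminant spike drawn from a packaged pseudo-phiX sequence;
* full ground-truth tables (contig provenance, read-pair provenance) so
  every downstream statistic can be checked against the generating truth.

Reads carry constant Q40 qualities by default; a decaying-tail quality
model exists solely to exercise the QC trimmer. Strandedness chemistry of
ssDNA viruses is not simulated — sequencing libraries are double-stranded
after MDA, so reads are generated as for dsDNA.

All outputs are reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fileio import package_data_path, read_fasta, revcomp
from .taxonomy import TaxonomyTable, default_taxonomy

__all__ = [
    "GenomeSpec",
    "CommunityConfig",
    "GroundTruth",
    "simulate_genomes",
    "fragment_sequence",
    "fragment_genomes",
    "simulate_read_pairs",
    "simulate_hits",
    "simulate_community",
    "mate_intervals",
    "junction_straddle_mask",
    "junction_straddle_fraction",
    "pseudo_phix",
    "stage_rng",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CONTAMINANT_ID = "contaminant"


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: an independent generator derived from (seed, stage).

    Lets one pipeline stage change its draws without perturbing another.
    """
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


def pseudo_phix() -> dict[str, str]:
    """The packaged synthetic 5,386 bp contaminant reference (circular)."""
    return read_fasta(package_data_path("pseudo_phix.fasta"))


@dataclass(frozen=True)
class GenomeSpec:
    """Identity and sampling weights of one simulated genome."""

    genome_id: str
    length: int
    topology: str  # "circular" | "linear"
    genome_class: str  # "ssDNA" | "dsDNA"
    taxon_id: str
    relative_abundance: float
    mda_factor: float = 1.0
    family_id: str | None = None


@dataclass(frozen=True)
class CommunityConfig:
    """Knobs of the synthetic community; ``seed`` is mandatory.

    Defaults mirror the study conditions the generator emulates: 174 b
    post-QC reads, a 10% contaminant spike, minimum contig length 200,
    and an MDA weight of 10 on circular ssDNA genomes.
    """

    seed: int
    n_genomes: int = 20
    ssdna_fraction: float = 0.5
    ssdna_length_range: tuple[int, int] = (4000, 7000)
    dsdna_length_range: tuple[int, int] = (30000, 60000)
    abundance_sigma: float = 1.5  # lognormal sigma; viromes are highly uneven
    gc_content: float = 0.5
    read_length: int = 174
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    n_read_pairs: int = 50_000
    error_rate: float = 0.0
    fragments_per_genome: tuple[int, int] = (3, 6)
    min_contig_length: int = 200
    contaminant_spike_fraction: float = 0.10
    mda_factor: float = 10.0
    genomes_per_family: int = 1  # >1 groups genomes into divergence families
    family_divergence: float = 0.05  # per-base substitution rate from ancestor
    quality_model: str = "constant"  # "constant" (Q40) | "decaying"

    def __post_init__(self) -> None:
        if self.n_genomes <= 0:
            raise ValueError("n_genomes must be positive")
        if self.n_read_pairs < 0:
            raise ValueError("n_read_pairs must be non-negative")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 <= self.contaminant_spike_fraction < 1.0:
            raise ValueError("contaminant_spike_fraction must be in [0, 1)")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be non-negative")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.fragments_per_genome[0] < 1:
            raise ValueError("fragments_per_genome must be >= 1")
        if self.mda_factor < 1:
            raise ValueError("mda_factor must be >= 1")
        if self.genomes_per_family < 1:
            raise ValueError("genomes_per_family must be >= 1")


@dataclass
class GroundTruth:
    """Provenance labels for simulated contigs and read pairs.

    ``contigs`` columns: contig_id, genome_id, start, length, end — 0-based
    half-open coordinates on the source genome; on circular genomes ``end``
    may exceed the genome length, meaning the contig wraps the origin.
    ``reads`` columns: pair_id, source_id (genome or "contaminant"), start,
    insert, strand — the fragment the pair was drawn from.
    """

    contigs: pd.DataFrame
    reads: pd.DataFrame


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_genomes(
    config: CommunityConfig,
    rng: np.random.Generator | None = None,
    taxonomy: TaxonomyTable | None = None,
) -> tuple[list[GenomeSpec], dict[str, str]]:
    """Draw the community: genome specs plus their sequences.

    Genomes are i.i.d. uniform-base sequences (at the configured GC);
    circular ssDNA genomes receive the MDA weight, linear dsDNA genomes a
    weight of 1. Abundances are lognormal draws normalized to sum to 1.
    When ``genomes_per_family > 1``, consecutive genomes of the same class
    are mutated copies of a shared ancestor at ``family_divergence``.
    """
    rng = stage_rng(config.seed, "genomes") if rng is None else rng
    taxonomy = taxonomy or default_taxonomy()
    n = config.n_genomes
    n_ss = int(round(n * config.ssdna_fraction))
    classes = ["ssDNA"] * n_ss + ["dsDNA"] * (n - n_ss)

    ss_taxa = taxonomy.species_under("ssdna") if "ssdna" in taxonomy else taxonomy.at_rank("species")
    ds_taxa = taxonomy.species_under("dsdna") if "dsdna" in taxonomy else taxonomy.at_rank("species")

    abundances = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    abundances /= abundances.sum()

    specs: list[GenomeSpec] = []
    seqs: dict[str, str] = {}
    family_seq: dict[str, str] = {}
    family_meta: dict[str, tuple[int, str]] = {}
    for i, cls in enumerate(classes):
        gid = f"g{i:03d}"
        topology = "circular" if cls == "ssDNA" else "linear"
        lo, hi = config.ssdna_length_range if cls == "ssDNA" else config.dsdna_length_range
        if lo < 2 * config.read_length:
            raise ValueError("genome length range must allow length >= 2 x read length")
        fam = None
        if config.genomes_per_family > 1:
            fam = f"fam_{cls}_{i // config.genomes_per_family:02d}"
        if fam is not None and fam in family_seq:
            length, taxon = family_meta[fam]
            seq = _mutate(family_seq[fam], config.family_divergence, rng)
        else:
            length = int(rng.integers(lo, hi + 1))
            pool = ss_taxa if cls == "ssDNA" else ds_taxa
            taxon = pool[int(rng.integers(0, len(pool)))]
            seq = _random_sequence(length, config.gc_content, rng)
            if fam is not None:
                family_seq[fam] = seq
                family_meta[fam] = (length, taxon)
        mda = config.mda_factor if (topology == "circular" and cls == "ssDNA") else 1.0
        specs.append(
            GenomeSpec(gid, length, topology, cls, taxon, float(abundances[i]), mda, fam)
        )
        seqs[gid] = seq
    return specs, seqs


# ---------------------------------------------------------------------------
# fragmentation ("assembly")
# ---------------------------------------------------------------------------

def fragment_sequence(
    seq: str, topology: str, breakpoints: Sequence[int]
) -> list[tuple[int, int, str]]:
    """Cut one genome at explicit breakpoints; returns (start, length, seq).

    Linear: k sorted breakpoints in (0, L) give k+1 contigs tiling [0, L).
    Circular: the first breakpoint linearizes the genome (a single
    breakpoint yields one full-length rotated contig); remaining
    breakpoints split the linearized sequence. Starts are genome
    coordinates modulo L.
    """
    L = len(seq)
    bps = sorted(set(int(b) for b in breakpoints))
    if any(b < 0 or b >= L for b in bps):
        raise ValueError(f"breakpoints out of range [0, {L})")
    if topology == "linear":
        if any(b == 0 for b in bps):
            raise ValueError("breakpoint 0 does not cut a linear genome")
        cuts = [0] + bps + [L]
        return [(cuts[i], cuts[i + 1] - cuts[i], seq[cuts[i] : cuts[i + 1]]) for i in range(len(cuts) - 1)]
    if topology == "circular":
        if not bps:
            raise ValueError("a circular genome needs at least one breakpoint to linearize")
        b0 = bps[0]
        rotated = seq[b0:] + seq[:b0]
        rel = [(b - b0) % L for b in bps[1:]]
        pieces = fragment_sequence(rotated, "linear", rel) if rel else [(0, L, rotated)]
        return [((s + b0) % L, ln, sub) for s, ln, sub in pieces]
    raise ValueError(f"unknown topology {topology!r}")


def _draw_breakpoints(
    L: int, n_fragments: int, min_len: int, topology: str, rng: np.random.Generator
) -> list[int]:
    """Breakpoints giving ``n_fragments`` pieces, each >= min_len.

    Segment lengths are min_len plus a uniform composition of the slack
    (sorted-uniform cutpoints), so no rejection sampling is needed.
    """
    k = n_fragments
    if k * min_len > L:
        raise ValueError(f"cannot cut length {L} into {k} fragments of >= {min_len}")
    slack = L - k * min_len
    cuts = np.sort(rng.integers(0, slack + 1, size=k - 1))
    seg = np.diff(np.concatenate([[0], cuts, [slack]])) + min_len
    if topology == "linear":
        return list(np.cumsum(seg)[:-1].astype(int))
    origin = int(rng.integers(0, L))
    return sorted((int(origin + s) % L) for s in np.concatenate([[0], np.cumsum(seg)[:-1]]))


def fragment_genomes(
    genomes: Sequence[GenomeSpec],
    sequences: Mapping[str, str],
    config: CommunityConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Fragment every genome into contigs; returns (contig seqs, truth table).

    Per-genome contig count is uniform on ``config.fragments_per_genome``;
    all contigs are at least ``config.min_contig_length`` long and tile the
    genome exactly (their lengths sum to the genome length).
    """
    rng = stage_rng(config.seed, "fragments") if rng is None else rng
    lo, hi = config.fragments_per_genome
    contigs: dict[str, str] = {}
    rows = []
    for g in genomes:
        seq = sequences[g.genome_id]
        k = int(rng.integers(lo, hi + 1))
        k = max(1, min(k, len(seq) // config.min_contig_length))
        if g.topology == "circular":
            bps = _draw_breakpoints(len(seq), k, config.min_contig_length, "circular", rng)
        else:
            bps = _draw_breakpoints(len(seq), k, config.min_contig_length, "linear", rng)
        for j, (start, length, sub) in enumerate(fragment_sequence(seq, g.topology, bps)):
            cid = f"{g.genome_id}_c{j:02d}"
            contigs[cid] = sub
            rows.append((cid, g.genome_id, start, length, start + length))
    truth = pd.DataFrame(rows, columns=["contig_id", "genome_id", "start", "length", "end"])
    return contigs, truth


# ---------------------------------------------------------------------------
# read pairs
# ---------------------------------------------------------------------------

def _quality(length: int, model: str, rng: np.random.Generator) -> str:
    if model == "constant":
        return "I" * length  # Q40
    if model == "decaying":
        # high-quality head, tail decaying 1 Q-unit per base down to Q2
        start = int(rng.integers(length // 2, length))
        q = np.full(length, 40, dtype=int)
        tail = np.arange(length - start)
        q[start:] = np.maximum(40 - 2 * (tail + 1), 2)
        return "".join(chr(33 + v) for v in q)
    raise ValueError(f"unknown quality model {model!r}")


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    return _mutate(seq, rate, rng)


def simulate_read_pairs(
    genomes: Sequence[GenomeSpec],
    sequences: Mapping[str, str],
    config: CommunityConfig,
    rng: np.random.Generator | None = None,
    contaminant: Mapping[str, str] | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate paired-end reads; returns (mates_1, mates_2, truth table).

    Source genomes are drawn with probability proportional to
    relative_abundance x mda_factor x length; fragment starts are uniform
    (wrapping the origin on circular genomes); the second mate is the
    reverse complement of the fragment's 3' end. A fraction of pairs is
    drawn from the contaminant reference (treated as circular).
    """
    if not genomes:
        raise ValueError("empty genome list")
    rng = stage_rng(config.seed, "reads") if rng is None else rng
    rl = config.read_length
    if contaminant is None and config.contaminant_spike_fraction > 0:
        contaminant = pseudo_phix()
    cont_seq = next(iter(contaminant.values())) if contaminant else ""

    w = np.array([g.relative_abundance * g.mda_factor * g.length for g in genomes], dtype=float)
    w /= w.sum()
    n = config.n_read_pairs
    is_cont = rng.random(n) < config.contaminant_spike_fraction
    source_idx = rng.choice(len(genomes), size=n, p=w)

    reads1: list[tuple[str, str, str]] = []
    reads2: list[tuple[str, str, str]] = []
    rows = []
    for i in range(n):
        pair_id = f"pair{i:06d}"
        if is_cont[i]:
            src_id, seq, topology = CONTAMINANT_ID, cont_seq, "circular"
        else:
            g = genomes[source_idx[i]]
            src_id, seq, topology = g.genome_id, sequences[g.genome_id], g.topology
        L = len(seq)
        if L < rl:
            raise ValueError(f"source {src_id} shorter than read length")
        frag = 0
        for _ in range(1000):
            frag = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            if rl <= frag <= L:
                break
        else:
            frag = min(max(frag, rl), L)
        if topology == "circular":
            s = int(rng.integers(0, L))
            fragment = (seq + seq)[s : s + frag]
        else:
            s = int(rng.integers(0, L - frag + 1))
            fragment = seq[s : s + frag]
        m1 = _apply_errors(fragment[:rl], config.error_rate, rng)
        m2 = _apply_errors(revcomp(fragment[-rl:]), config.error_rate, rng)
        reads1.append((f"{pair_id}/1", m1, _quality(rl, config.quality_model, rng)))
        reads2.append((f"{pair_id}/2", m2, _quality(rl, config.quality_model, rng)))
        rows.append((pair_id, src_id, s, frag, "+"))
    truth = pd.DataFrame(rows, columns=["pair_id", "source_id", "start", "insert", "strand"])
    return reads1, reads2, truth


# ---------------------------------------------------------------------------
# ground-truth geometry helpers
# ---------------------------------------------------------------------------

def mate_intervals(read_truth: pd.DataFrame, read_length: int) -> pd.DataFrame:
    """Per-mate source intervals (start, mod genome length for circular)."""
    rows = []
    for t in read_truth.itertuples(index=False):
        rows.append((t.pair_id, 1, t.source_id, t.start))
        rows.append((t.pair_id, 2, t.source_id, t.start + t.insert - read_length))
    return pd.DataFrame(rows, columns=["pair_id", "mate", "source_id", "start"])


def junction_straddle_mask(
    read_truth: pd.DataFrame,
    contig_truth: pd.DataFrame,
    genomes: Sequence[GenomeSpec],
    read_length: int,
) -> pd.DataFrame:
    """Flag, per mate, whether it straddles a contig boundary of its genome.

    A mate straddles iff some contig start lies strictly inside its source
    interval (computed modulo the genome length so origin-wrapping mates on
    circular genomes are handled). Straddling mates are exactly the mates
    the zero-mismatch full-length mapper cannot place; contaminant mates
    are never straddling (the contaminant is not assembled).
    """
    by_genome = {g.genome_id: g for g in genomes}
    starts = {gid: grp["start"].tolist() for gid, grp in contig_truth.groupby("genome_id")}
    mates = mate_intervals(read_truth, read_length)
    flags = []
    for t in mates.itertuples(index=False):
        if t.source_id not in by_genome:
            flags.append(False)
            continue
        L = by_genome[t.source_id].length
        s = t.start % L
        straddle = any(0 < (b - s) % L < read_length for b in starts.get(t.source_id, ()))
        flags.append(straddle)
    mates["straddles"] = flags
    return mates


def junction_straddle_fraction(
    read_truth: pd.DataFrame,
    contig_truth: pd.DataFrame,
    genomes: Sequence[GenomeSpec],
    read_length: int,
) -> float:
    mask = junction_straddle_mask(read_truth, contig_truth, genomes, read_length)
    return float(mask["straddles"].mean()) if len(mask) else 0.0


# ---------------------------------------------------------------------------
# truth-driven homology hit tables
# ---------------------------------------------------------------------------

_GENE_PRODUCTS = (
    "capsid protein",
    "replication initiation protein",
    "rep protein",
    "portal protein",
    "terminase large subunit",
    "integrase",
    "assembly protein",
    "hypothetical protein",
)


def simulate_hits(
    contig_truth: pd.DataFrame,
    genomes: Sequence[GenomeSpec],
    taxonomy: TaxonomyTable | None = None,
    rng: np.random.Generator | None = None,
    detection_rate: float = 0.4,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Homology-hit table derived from ground truth (a BLAST stand-in).

    Each contig yields a hit to its source genome's taxon with probability
    ``detection_rate`` (so a dropout of 1 - detection_rate of contigs stays
    "unknown" before network propagation); ``noise_rate`` adds off-target
    hits to random taxa at marginal e-values. Columns match the hit-TSV
    interface: contig_id, taxon_id, e_value, gene_product.
    """
    taxonomy = taxonomy or default_taxonomy()
    rng = np.random.default_rng([seed, zlib.crc32(b"hits")]) if rng is None else rng
    taxon_of = {g.genome_id: g.taxon_id for g in genomes}
    all_taxa = sorted(taxonomy.nodes)
    rows = []
    for t in contig_truth.itertuples(index=False):
        if rng.random() < detection_rate:
            e = 10.0 ** rng.uniform(-30, -4)
            product = _GENE_PRODUCTS[int(rng.integers(0, len(_GENE_PRODUCTS)))]
            rows.append((t.contig_id, taxon_of[t.genome_id], e, product))
        if noise_rate > 0 and rng.random() < noise_rate:
            e = 10.0 ** rng.uniform(-6, -2)
            taxon = all_taxa[int(rng.integers(0, len(all_taxa)))]
            rows.append((t.contig_id, taxon, e, "hypothetical protein"))
    return pd.DataFrame(rows, columns=["contig_id", "taxon_id", "e_value", "gene_product"])


# ---------------------------------------------------------------------------
# convenience: one-call community
# ---------------------------------------------------------------------------

def simulate_community(
    config: CommunityConfig,
    taxonomy: TaxonomyTable | None = None,
) -> tuple[list[GenomeSpec], dict[str, str], dict[str, str], GroundTruth,
           list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Simulate genomes, contigs and read pairs in one seeded call.

    Returns (genome specs, genome seqs, contig seqs, ground truth,
    mates_1, mates_2). Each stage uses its own named substream of
    ``config.seed``.
    """
    specs, seqs = simulate_genomes(config, taxonomy=taxonomy)
    contigs, contig_truth = fragment_genomes(specs, seqs, config)
    reads1, reads2, read_truth = simulate_read_pairs(specs, seqs, config)
    return specs, seqs, contigs, GroundTruth(contig_truth, read_truth), reads1, reads2
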