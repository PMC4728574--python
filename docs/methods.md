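# Methods

## The contig-network model

Let reads be mapped to contigs under the *exact contract*: a mate is
placed iff its sequence (or reverse complement) occurs as an exact
substring of a contig, i.e. it aligns over its entire length with zero
mismatches. Build the undirected graph G whose vertices are contigs and
where an edge {u, v}, u ≠ v, carries weight equal to the number of read
pairs with one mate placed on u and the other on v. Connected components
of G with at least two members are *networks*; under the exact contract
an edge certifies that u and v share ≥ one read length of sequence at
100% identity, so a network is interpreted as a set of closely related
genome fragments — related at roughly (sub)family level or above, not a
single genome. Components are computed by union-find and numbered
deterministically (descending size, ties by smallest member id).

Taxonomic assignment is two-step. Per contig: the taxon of the
minimum-e-value homology hit among hits with e < 0.001 (strict), exact
ties collapsing to the lowest common ancestor (LCA) of the tied taxa.
Per network: the LCA of all directly annotated members — one annotated
member suffices, and conflicting annotations fall back to a higher
taxon. Propagation then copies the network taxon onto unannotated
members (never overwriting a direct annotation); the *annotation gain*
is the drop in the number of unknown contigs. The taxonomy mixes formal
ranks with informal groups ("ssDNA viruses", "bacteria") directly under
the root, because environmental annotations often resolve only to such
groups; "unknown" is the absence of assignment, not a taxon. LCA
operates on parent paths, so rank-skipping lineages are fine.

Between-virome similarity uses two measures. (i) Directional
cross-mapping: the fraction of virome i's reads that place exactly on
virome j's contigs (unpaired mode); the matrix is not symmetrized.
(ii) Presence/absence Bray-Curtis on species-rank annotation profiles:
d = (b + c) / (2a + b + c) with a shared and b, c unique species —
identically the Sørensen dissimilarity — followed by agglomerative
clustering (complete linkage by default; single and average available).
Presence/absence rather than abundance is used because whole-genome
amplification distorts abundances.

## Numerical and algorithmic choices

* **Matcher.** Exact placement is k-mer anchored (default k = 31): every
  contig k-mer is indexed; a query is anchored by its leading k-mer on
  each strand and verified by direct comparison; queries shorter than k
  fall back to a linear scan. Multi-mapping tie-break: smallest
  contig id, then smallest start, then '+' before '−' — chosen so
  results are independent of read and contig order (real aligners pick
  randomized best hits; determinism is worth more here than emulating
  that).
* **SAM import** keeps only primary records that are mapped, have
  CIGARs made entirely of match operations covering the whole read, and
  NM = 0 (records without NM are accepted only with '='-only CIGARs,
  else skipped with a warning). Coordinates convert from 1-based SAM to
  0-based internal.
* **QC trimming** cuts at the first sliding window (width 4) whose mean
  quality is below the threshold (Q25); the quality floor is applied to
  the post-trim mean by default (a per-base variant is available by
  flag). Minimum post-trim length 150 b.
* **Coverage** is mean depth (mapped bases / contig length); per-network
  mean coverage is the *unweighted* mean of member coverages
  (length-weighting would be the alternative; the unweighted choice is
  logged here once and used consistently).
* **Spotlight filter** is strict: max member coverage > 1000 (a network
  at exactly 1000x is not flagged).
* **Edge threshold** `min_pairs` defaults to 1 (no thresholding);
  raising it can only split networks, never merge them.
* **Clustering** is the naive O(n³) agglomerator operating on the
  original dissimilarities; ties break toward the earliest-created
  cluster pair, making merge order deterministic even on the rational
  tie-prone values presence/absence data produces. Newick branch
  lengths are merge-height differences. Virome counts are small, so
  cubic cost is irrelevant.
* **Degenerate inputs.** Two empty profiles get dissimilarity 0 with a
  warning (so clustering never fails on degenerate runs); an empty read
  set yields a missing (NaN) cross-mapping row with a warning;
  mapped_fraction on zero reads is an error.

## The synthetic community generator

The generator emulates the data structure of an MDA-amplified,
short-read-sequenced environmental virome; defaults (one-time choices,
with units):

| parameter | default | rationale |
|---|---|---|
| n_genomes | 20 | desk-scale community |
| ssDNA fraction | 0.5 | mixed ssDNA/dsDNA community |
| ssDNA genome length | 4–7 kb, circular | Microviridae/Circoviridae scale |
| dsDNA genome length | 30–60 kb, linear | tailed-phage scale |
| abundance model | lognormal, σ = 1.5 | virome abundances span orders of magnitude |
| mda_factor | 10 (circular ssDNA only) | the preferential amplification of circular ssDNA templates is reported qualitatively, not quantitatively; a single multiplicative weight is a free parameter capturing its downstream footprint (inflated ssDNA coverages), not a chemistry simulation |
| read length | 174 b | post-QC short-read length |
| insert | normal(400, 50) b, truncated to [read length, genome length] | typical short-insert library |
| error rate | 0 | post-QC idealization; under the exact contract an erroneous mate is simply unmapped, so error acts as a uniform thinning of mapped reads |
| contaminant spike | 10% of pairs | control-spike fraction common in sequencing runs; drawn from a packaged *synthetic* 5,386 b pseudo-phiX sequence (randomly generated, shipped to avoid external data) |
| fragments per genome | uniform 3–6, min contig 200 b | produces multi-contig genomes joined by junction-spanning pairs |
| qualities | constant Q40 | the decaying-tail model exists only to exercise the trimmer |

Source genomes of read pairs are drawn with probability proportional to
relative_abundance × mda_factor × length; fragment starts are uniform
and wrap the origin on circular genomes; the second mate is the reverse
complement of the fragment's 3' end. Fragmentation draws segment
lengths as minimum-length-plus-uniform-composition, so contigs tile each
genome exactly and no rejection sampling is needed; a circular genome's
first breakpoint linearizes it (one breakpoint = one full-length rotated
contig). Ground-truth tables record contig intervals and read-pair
provenance, which yields an exact closure identity used in testing: with
zero error and no spike, the self-mapping fraction equals one minus the
fraction of mates whose source interval contains a contig boundary
strictly inside it.

Randomness: every stage draws from a named substream of the config seed
(generator seeded with `[seed, crc32(stage)]`), so changing one stage's
settings cannot perturb another's draws; all outputs are bit-for-bit
reproducible from (config, seed).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no indels or chimeras, no GC- or
position-dependent error, no branching-process MDA (no within-genome
coverage waves), no strand chemistry for ssDNA genomes (libraries are
double-stranded after amplification), no real assembler (fragmentation
is clean tiling: real contigs overlap, misassemble, and collapse
repeats), random sequence composition (no codon structure, no repeats —
so cross-genome exact matches are vanishingly rare and network purity is
structurally easier than in nature), and hit tables derived from truth
rather than from a decaying database homology signal.

## Problem sizes used in validation

The demonstration configuration is two viromes × 20 genomes × 50,000
read pairs (hit-table dropout 0.6), which the package treats as its
standard desk-scale experiment; network-recovery checks use 20
equal-abundance genomes at ~80-fold read depth so that every
inter-contig junction is expected to be spanned ~12 times (Poisson
argument: spanning window ≈ insert − 2 × read length ≈ 52 b); the MDA
experiment uses two 6 kb genomes and 20,000 pairs, giving a 3-SE band of
about ±0.75 around the expected 10:1 ratio.

## Known limitations

* The exact-match contract means any sequencing error unmaps a read;
  real aligner presets tolerate search-effort differences the contract
  ignores. Cross-virome mapped fractions between *independently
  generated* communities are therefore ~0, unlike related natural
  communities, which share sequence.
* Contaminant removal screens reads only; removing near-identical
  *contigs* would need an approximate aligner and is out of scope.
* The spotlight-flag count at demo scale (0–2 networks) is seed
  dependent: whether a network exceeds 1000x depends on the abundance
  draw's upper tail.
* One taxon per contig: multi-species hits expand to a single
  (tie-LCA) taxon before profiling.
* Unpaired cross-mapping does not de-duplicate reads before counting.
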