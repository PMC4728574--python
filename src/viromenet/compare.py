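"""Between-virome comparison: cross-mapping fractions and presence/absence
Bray-Curtis clustering.

Two complementary similarity measures:

* **Cross-mapping**: the fraction of one virome's reads that place
  (full-length, zero mismatches, unpaired) on another virome's contigs.
  The matrix is directional — reads-to-contigs — and is deliberately not
  symmetrized.
* **Presence/absence Bray-Curtis**: each virome is reduced to the set of
  species-rank taxa among its contig annotations (direct plus
  propagated); presence/absence rather than abundance because whole-
  genome amplification distorts abundances. On 0/1 data the Bray-Curtis
  dissimilarity d = (b + c) / (2a + b + c) — a shared species, b and c
  unique to either side — which is identically the Sorensen
  dissimilarity. Profiles are then clustered agglomeratively
  (complete linkage by default, single/average available) and exported
  as a Newick dendrogram whose branch lengths are merge-height
  differences.

The agglomerator is the plain O(n^3) scheme with a deterministic
tie-break (among minimum-distance cluster pairs, the pair with the
smallest creation indices merges first), so merge order is reproducible
even on tied dissimilarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import UNKNOWN, ContigAnnotation
from .mapping import ExactMatcher, map_reads_exact, mapped_fraction
from .taxonomy import TaxonomyTable

__all__ = [
    "ViromeProfile",
    "DissimilarityMatrix",
    "cross_mapping_matrix",
    "presence_absence",
    "bray_curtis",
    "pairwise_bray_curtis",
    "cluster_viromes",
    "profiles_to_frame",
]


@dataclass(frozen=True)
class ViromeProfile:
    virome_id: str
    species_present: frozenset[str]


@dataclass
class DissimilarityMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("entries must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


# ---------------------------------------------------------------------------
# cross-mapping
# ---------------------------------------------------------------------------

def cross_mapping_matrix(
    read_sets: Mapping[str, Sequence[Sequence[str]]],
    contig_sets: Mapping[str, Mapping[str, str]],
    k: int = 31,
) -> pd.DataFrame:
    """Entry (i, j): mapped fraction of read set i against contig set j,
    unpaired exact mapping. Empty read sets give NaN (reported missing)."""
    if not read_sets or not contig_sets:
        raise ValueError("need at least one read set and one contig set")
    matchers = {name: ExactMatcher(contigs, k=k) for name, contigs in contig_sets.items()}
    out = pd.DataFrame(
        np.nan, index=list(read_sets), columns=list(contig_sets), dtype=float
    )
    for rname, reads in read_sets.items():
        if len(reads) == 0:
            warnings.warn(f"read set {rname!r} is empty; row reported as missing")
            continue
        for cname, matcher in matchers.items():
            result = map_reads_exact(list(reads), matcher, mode="unpaired")
            out.loc[rname, cname] = mapped_fraction(result)
    return out


# ---------------------------------------------------------------------------
# presence/absence profiles
# ---------------------------------------------------------------------------

def presence_absence(
    annotations_by_virome: Mapping[str, Mapping[str, ContigAnnotation]],
    taxonomy: TaxonomyTable,
    rank: str = "species",
) -> list[ViromeProfile]:
    """Reduce each virome's contig annotations (direct + propagated) to the
    set of taxa at exactly ``rank``; annotations above that rank are
    excluded, and "unknown" is absence, not a taxon."""
    if rank not in taxonomy.rank_order:
        raise ValueError(f"unknown rank {rank!r}")
    profiles = []
    for vid, annotations in annotations_by_virome.items():
        present = {
            a.taxon_id
            for a in annotations.values()
            if a.taxon_id != UNKNOWN and taxonomy.rank(a.taxon_id) == rank
        }
        profiles.append(ViromeProfile(vid, frozenset(present)))
    return profiles


def profiles_to_frame(profiles: Sequence[ViromeProfile]) -> pd.DataFrame:
    rows = [(p.virome_id, t) for p in profiles for t in sorted(p.species_present)]
    return pd.DataFrame(rows, columns=["virome_id", "taxon_id"])


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def pairwise_bray_curtis(x: frozenset[str] | set[str], y: frozenset[str] | set[str]) -> float:
    """Presence/absence Bray-Curtis d = (b + c) / (2a + b + c); defined as
    0 for two empty sets (with a warning at the matrix level)."""
    a = len(x & y)
    b = len(x - y)
    c = len(y - x)
    denom = 2 * a + b + c
    return (b + c) / denom if denom else 0.0


def bray_curtis(profiles: Sequence[ViromeProfile]) -> DissimilarityMatrix:
    if len(profiles) < 2:
        raise ValueError("bray_curtis requires at least two profiles")
    n = len(profiles)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = profiles[i].species_present, profiles[j].species_present
            if not x and not y:
                warnings.warn(
                    f"both {profiles[i].virome_id!r} and {profiles[j].virome_id!r} are empty; "
                    "dissimilarity set to 0"
                )
            v[i, j] = v[j, i] = pairwise_bray_curtis(x, y)
    return DissimilarityMatrix(tuple(p.virome_id for p in profiles), v)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def _cluster_distance(
    members_a: Sequence[int], members_b: Sequence[int], d: np.ndarray, linkage: str
) -> float:
    pairs = [d[i, j] for i in members_a for j in members_b]
    if linkage == "complete":
        return max(pairs)
    if linkage == "single":
        return min(pairs)
    if linkage == "average":
        return sum(pairs) / len(pairs)
    raise ValueError(f"unknown linkage {linkage!r}")


def cluster_viromes(
    matrix: DissimilarityMatrix, linkage: str = "complete"
) -> tuple[str, list[dict]]:
    """Agglomerative clustering of the dissimilarity matrix.

    Returns (newick, merges). Leaves are the virome ids; each merge record
    gives the two cluster indices joined (leaves are 0..n-1, new clusters
    continue upward in creation order), the merge height, and the leaf
    members of the new cluster. Newick branch lengths are the difference
    between a cluster's merge height and its children's heights.
    """
    n = len(matrix.ids)
    if n < 2:
        raise ValueError("clustering requires at least two viromes")
    d = matrix.values
    # active clusters: index -> leaf members; heights/newick per cluster index
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    newick: dict[int, str] = {i: matrix.ids[i] for i in range(n)}
    active = list(range(n))
    merges: list[dict] = []
    next_id = n
    while len(active) > 1:
        best: tuple[float, int, int] | None = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                dist = _cluster_distance(members[i], members[j], d, linkage)
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        assert best is not None
        dist, i, j = best
        members[next_id] = members[i] + members[j]
        height[next_id] = dist
        bl_i = dist - height[i]
        bl_j = dist - height[j]
        newick[next_id] = f"({newick[i]}:{bl_i:.6g},{newick[j]}:{bl_j:.6g})"
        merges.append(
            {
                "clusters": (i, j),
                "height": dist,
                "members": [matrix.ids[m] for m in sorted(members[next_id])],
            }
        )
        active = [x for x in active if x not in (i, j)] + [next_id]
        next_id += 1
    return newick[active[0]] + ";", merges
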