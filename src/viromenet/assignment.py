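"""Taxonomic assignment of contigs and networks, with LCA fallback.

Homology hits (a BLAST-style TSV of contig, taxon, e-value, gene product)
are filtered at a strict e-value threshold (< 0.001). Each contig takes
the taxon of its best (minimum e-value) hit; exact ties are resolved to
the lowest common ancestor of the tied taxa. A network is assigned as
soon as at least one member contig carries a direct annotation: its taxon
is the LCA of all directly annotated members, so conflicting family-level
annotations fall back to a higher taxon (e.g. two members hitting
different tailed-phage families yield the order). Networks with no
annotated member stay "unknown".

Propagation then copies each network's taxon onto its unannotated
members, which is where the annotation gain comes from: the gain report
counts unknown contigs before and after. Propagation never overwrites a
direct annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .network import NetworkPartition
from .taxonomy import TaxonomyTable

__all__ = [
    "UNKNOWN",
    "HitRecord",
    "ContigAnnotation",
    "NetworkAssignment",
    "read_hits",
    "hits_from_frame",
    "write_hits",
    "assign_contigs",
    "assign_networks",
    "propagate",
    "tally_marker",
    "network_summary",
    "lca_diagnostics",
]

#: Sentinel for "no assignment"; absence of annotation, not a taxon.
UNKNOWN = "unknown"


@dataclass(frozen=True)
class HitRecord:
    contig_id: str
    taxon_id: str
    e_value: float
    gene_product: str = ""

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


@dataclass(frozen=True)
class ContigAnnotation:
    taxon_id: str  # a taxon id or UNKNOWN
    provenance: str  # "direct" | "propagated" | "none"


@dataclass(frozen=True)
class NetworkAssignment:
    network_id: int
    taxon_id: str  # LCA of supporting contigs' taxa, or UNKNOWN
    supporting: tuple[str, ...]  # directly annotated member contigs
    marker_genes: tuple[str, ...]  # distinct non-empty gene products


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def hits_from_frame(
    frame: pd.DataFrame, taxonomy: TaxonomyTable, e_max: float = 0.001
) -> tuple[list[HitRecord], list[dict]]:
    """Filter a hit table at ``e_value < e_max`` (strict); rows whose taxon
    does not resolve in the taxonomy go to a rejects list, not an error."""
    hits: list[HitRecord] = []
    rejects: list[dict] = []
    for row in frame.itertuples(index=False):
        e = float(row.e_value)
        if not e < e_max:
            continue
        if row.taxon_id not in taxonomy:
            rejects.append(
                {"contig_id": row.contig_id, "taxon_id": row.taxon_id, "reason": "unresolvable taxon"}
            )
            continue
        product = "" if pd.isna(row.gene_product) else str(row.gene_product)
        hits.append(HitRecord(str(row.contig_id), str(row.taxon_id), e, product))
    return hits, rejects


def read_hits(
    path: str, taxonomy: TaxonomyTable, e_max: float = 0.001
) -> tuple[list[HitRecord], list[dict]]:
    """Read a hit TSV (contig_id, taxon_id, e_value, gene_product) and
    filter it; see :func:`hits_from_frame`."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"contig_id": str, "taxon_id": str, "gene_product": str}
    )
    required = {"contig_id", "taxon_id", "e_value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"hit TSV must have columns {sorted(required)}")
    if "gene_product" not in frame.columns:
        frame["gene_product"] = ""
    return hits_from_frame(frame, taxonomy, e_max)


def write_hits(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# contig- and network-level assignment
# ---------------------------------------------------------------------------

def assign_contigs(
    hits: Sequence[HitRecord],
    taxonomy: TaxonomyTable,
    contig_ids: Iterable[str] | None = None,
) -> dict[str, ContigAnnotation]:
    """Direct per-contig taxa: the minimum-e-value hit's taxon; exact
    e-value ties collapse to the LCA of the tied taxa. Contigs listed in
    ``contig_ids`` but without hits are annotated UNKNOWN."""
    by_contig: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    out: dict[str, ContigAnnotation] = {}
    for cid, hs in by_contig.items():
        best = min(h.e_value for h in hs)
        tied = {h.taxon_id for h in hs if h.e_value == best}
        taxon = taxonomy.lca(tied) if len(tied) > 1 else next(iter(tied))
        out[cid] = ContigAnnotation(taxon, "direct")
    if contig_ids is not None:
        for cid in contig_ids:
            out.setdefault(cid, ContigAnnotation(UNKNOWN, "none"))
    return out


def assign_networks(
    partition: NetworkPartition,
    annotations: Mapping[str, ContigAnnotation],
    taxonomy: TaxonomyTable,
    hits: Sequence[HitRecord] | None = None,
) -> dict[int, NetworkAssignment]:
    """Per-network taxon: the LCA of all directly annotated members, or
    UNKNOWN when no member has a direct annotation (one annotated contig
    suffices to assign the whole network). Marker genes are the distinct
    non-empty gene products of member hits, when hits are supplied.
    Singleton contigs are not networks and keep their direct annotation."""
    products: dict[str, set[str]] = {}
    for h in hits or ():
        if h.gene_product:
            products.setdefault(h.contig_id, set()).add(h.gene_product)
    out: dict[int, NetworkAssignment] = {}
    for net in partition.networks:
        direct = [
            (c, annotations[c].taxon_id)
            for c in net.members
            if c in annotations
            and annotations[c].provenance == "direct"
            and annotations[c].taxon_id != UNKNOWN
        ]
        if direct:
            taxon = taxonomy.lca([t for _, t in direct])
            supporting = tuple(c for c, _ in direct)
        else:
            taxon, supporting = UNKNOWN, ()
        markers = sorted({p for c in net.members for p in products.get(c, ())})
        out[net.network_id] = NetworkAssignment(net.network_id, taxon, supporting, tuple(markers))
    return out


def propagate(
    partition: NetworkPartition,
    annotations: Mapping[str, ContigAnnotation],
    network_assignments: Mapping[int, NetworkAssignment],
) -> tuple[dict[str, ContigAnnotation], dict]:
    """Copy each assigned network's taxon onto its unannotated members.

    Direct annotations are never overwritten. The gain report counts
    contigs of the partition (network members plus singletons) that are
    unknown before and after propagation.
    """
    updated = dict(annotations)
    universe = [c for net in partition.networks for c in net.members]
    universe += sorted(partition.singletons)
    for cid in universe:
        updated.setdefault(cid, ContigAnnotation(UNKNOWN, "none"))

    def n_unknown(ann: Mapping[str, ContigAnnotation]) -> int:
        return sum(1 for c in universe if ann[c].taxon_id == UNKNOWN)

    before = n_unknown(updated)
    for net in partition.networks:
        na = network_assignments.get(net.network_id)
        if na is None or na.taxon_id == UNKNOWN:
            continue
        for cid in net.members:
            if updated[cid].taxon_id == UNKNOWN:
                updated[cid] = ContigAnnotation(na.taxon_id, "propagated")
    after = n_unknown(updated)
    report = {
        "n_contigs_considered": len(universe),
        "unknown_before": before,
        "unknown_after": after,
    }
    return updated, report


def tally_marker(hits: Sequence[HitRecord], keyword: str) -> int:
    """Number of distinct contigs whose gene product contains ``keyword``
    (case-insensitive substring; a contig with several matching hits
    counts once)."""
    if not keyword:
        raise ValueError("keyword must be non-empty")
    kw = keyword.lower()
    return len({h.contig_id for h in hits if kw in h.gene_product.lower()})


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def network_summary(
    partition: NetworkPartition,
    assignments: Mapping[int, NetworkAssignment],
    taxonomy: TaxonomyTable,
) -> pd.DataFrame:
    """Per-network summary table: id, size, max/mean coverage, assignment
    (display name), marker genes."""
    rows = []
    for net in partition.networks:
        na = assignments.get(net.network_id)
        taxon = na.taxon_id if na else UNKNOWN
        name = taxonomy.name(taxon) if taxon != UNKNOWN else UNKNOWN
        markers = "; ".join(na.marker_genes) if na and na.marker_genes else "-"
        rows.append(
            (net.network_id, net.n_contigs, net.max_coverage, net.mean_coverage, name, markers)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "network_id",
            "n_contigs",
            "max_coverage",
            "mean_coverage",
            "assignment",
            "marker_genes",
        ],
    )


def lca_diagnostics(
    assignments: Mapping[int, NetworkAssignment], taxonomy: TaxonomyTable
) -> list[int]:
    """Networks whose LCA climbed above family rank — conflicting member
    annotations absorbed by the higher-taxon fallback, worth a look."""
    ranks = {r: i for i, r in enumerate(taxonomy.rank_order)}
    family_i = ranks["family"]
    out = []
    for na in assignments.values():
        if na.taxon_id == UNKNOWN or not na.supporting:
            continue
        if ranks[taxonomy.rank(na.taxon_id)] < family_i and len(na.supporting) > 1:
            out.append(na.network_id)
    return sorted(out)
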