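"""Contig networks from paired read mappings.

Nodes are contigs (with length and fold coverage); an undirected edge
joins two distinct contigs whenever a read pair has one full-length
zero-mismatch mate on each, weighted by the number of supporting pairs.
Connected components of at least two contigs are the "networks" — groups
of taxonomically related genome fragments, not single genomes. Pairs with
both mates on the same contig contribute to coverage only, never to
edges; no self-loops exist. No composition-based (tetranucleotide or
coverage) binning is performed anywhere.

Networks are numbered deterministically: sorted by descending size, ties
broken by the smallest member contig id. The spotlight filter flags
networks whose maximum member coverage strictly exceeds a threshold
(default 1000-fold). Per-network mean coverage is the unweighted mean of
member coverages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .mapping import MappingResult

__all__ = [
    "ContigNode",
    "ContigGraph",
    "Network",
    "NetworkPartition",
    "build_graph",
    "extract_networks",
    "flag_high_coverage",
    "export_cytoscape",
    "read_cytoscape",
    "partition_to_json",
    "partition_from_json",
]


@dataclass(frozen=True)
class ContigNode:
    contig_id: str
    length: int
    coverage: float


@dataclass
class ContigGraph:
    """Undirected weighted graph over contigs.

    Edge keys are sorted (a, b) tuples with a < b; weights are supporting
    read-pair counts.
    """

    nodes: dict[str, ContigNode]
    edges: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"edge key {(a, b)} not sorted")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge {(a, b)} references unknown node")
            if w < 1:
                raise ValueError(f"edge {(a, b)} has non-positive weight")


@dataclass(frozen=True)
class Network:
    network_id: int
    members: tuple[str, ...]  # sorted contig ids, len >= 2
    n_contigs: int
    max_coverage: float
    mean_coverage: float


@dataclass
class NetworkPartition:
    """Networks (components of size >= 2) plus singleton contigs.

    Together they partition the full contig set of the graph.
    """

    networks: list[Network]
    singletons: frozenset[str]

    @property
    def n_contigs(self) -> int:
        return sum(n.n_contigs for n in self.networks) + len(self.singletons)

    def members_of(self, network_id: int) -> tuple[str, ...]:
        for n in self.networks:
            if n.network_id == network_id:
                return n.members
        raise KeyError(f"no network {network_id}")


def build_graph(
    result: MappingResult,
    contigs: Mapping[str, str],
    coverage: Mapping[str, float],
    min_pairs: int = 1,
) -> ContigGraph:
    """Count, per read pair with both mates mapped to distinct contigs,
    one support for that edge; drop edges supported by fewer than
    ``min_pairs`` pairs (default 1, i.e. no thresholding)."""
    if result.mode != "paired":
        raise ValueError("build_graph requires a paired mapping result")
    missing = [cid for cid in contigs if cid not in coverage]
    if missing:
        raise ValueError(f"coverage missing for contigs {missing[:3]}...")
    mates: dict[str, dict[int, str]] = {}
    for rec in result.records:
        mates.setdefault(rec.pair_id, {})[rec.mate] = rec.contig_id
    weights: dict[tuple[str, str], int] = {}
    for placed in mates.values():
        if 1 in placed and 2 in placed and placed[1] != placed[2]:
            key = tuple(sorted((placed[1], placed[2])))
            weights[key] = weights.get(key, 0) + 1
    edges = {k: w for k, w in weights.items() if w >= min_pairs}
    nodes = {
        cid: ContigNode(cid, len(seq), float(coverage[cid])) for cid, seq in contigs.items()
    }
    return ContigGraph(nodes, edges)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def extract_networks(graph: ContigGraph) -> NetworkPartition:
    """Connected components via union-find; size-1 components are
    singletons. Networks are ordered by descending size, ties by smallest
    member id, and numbered from 1."""
    uf = _UnionFind(graph.nodes)
    for a, b in graph.edges:
        uf.union(a, b)
    comps: dict[str, list[str]] = {}
    for cid in graph.nodes:
        comps.setdefault(uf.find(cid), []).append(cid)
    multi = sorted(
        (sorted(members) for members in comps.values() if len(members) >= 2),
        key=lambda m: (-len(m), m[0]),
    )
    networks = []
    for i, members in enumerate(multi, start=1):
        covs = [graph.nodes[c].coverage for c in members]
        networks.append(
            Network(i, tuple(members), len(members), max(covs), sum(covs) / len(covs))
        )
    singles = frozenset(m[0] for m in comps.values() if len(m) == 1)
    return NetworkPartition(networks, singles)


def flag_high_coverage(
    partition: NetworkPartition,
    coverage: Mapping[str, float] | None = None,
    threshold: float = 1000.0,
) -> tuple[list[int], pd.DataFrame]:
    """Flag networks whose maximum member coverage strictly exceeds
    ``threshold``. Returns (flagged network ids, per-network stats table).

    When ``coverage`` is given, max/mean are recomputed from it; otherwise
    the stats stored on the partition are used.
    """
    rows = []
    flagged = []
    for net in partition.networks:
        if coverage is not None:
            covs = [coverage[c] for c in net.members]
            mx, mean = max(covs), sum(covs) / len(covs)
        else:
            mx, mean = net.max_coverage, net.mean_coverage
        is_flagged = mx > threshold
        if is_flagged:
            flagged.append(net.network_id)
        rows.append((net.network_id, net.n_contigs, mx, mean, is_flagged))
    stats = pd.DataFrame(
        rows, columns=["network_id", "n_contigs", "max_coverage", "mean_coverage", "flagged"]
    )
    return flagged, stats


# ---------------------------------------------------------------------------
# Cytoscape-style exports
# ---------------------------------------------------------------------------

def export_cytoscape(graph: ContigGraph, partition: NetworkPartition, out_prefix: str) -> tuple[str, str]:
    """Write edge and node-attribute TSVs loadable by network viewers.

    ``<prefix>.edges.tsv``: source, target, weight.
    ``<prefix>.nodes.tsv``: contig_id, length, coverage, network_id
    (or "singleton").
    """
    net_of: dict[str, str] = {c: "singleton" for c in partition.singletons}
    for net in partition.networks:
        for c in net.members:
            net_of[c] = str(net.network_id)
    edge_path = f"{out_prefix}.edges.tsv"
    node_path = f"{out_prefix}.nodes.tsv"
    with open(edge_path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for (a, b), w in sorted(graph.edges.items()):
            fh.write(f"{a}\t{b}\t{w}\n")
    with open(node_path, "w") as fh:
        fh.write("contig_id\tlength\tcoverage\tnetwork_id\n")
        for cid in sorted(graph.nodes):
            node = graph.nodes[cid]
            fh.write(f"{cid}\t{node.length}\t{node.coverage:.6g}\t{net_of.get(cid, 'singleton')}\n")
    return edge_path, node_path


def read_cytoscape(out_prefix: str) -> ContigGraph:
    """Reconstruct a ContigGraph from exported edge/node tables."""
    nodes_df = pd.read_csv(f"{out_prefix}.nodes.tsv", sep="\t")
    edges_df = pd.read_csv(f"{out_prefix}.edges.tsv", sep="\t")
    nodes = {
        str(r.contig_id): ContigNode(str(r.contig_id), int(r.length), float(r.coverage))
        for r in nodes_df.itertuples(index=False)
    }
    edges = {
        tuple(sorted((str(r.source), str(r.target)))): int(r.weight)
        for r in edges_df.itertuples(index=False)
    }
    return ContigGraph(nodes, edges)


def partition_to_json(partition: NetworkPartition, path: str | None = None) -> dict:
    """JSON-serializable view mirroring the per-network summary schema."""
    doc = {
        "networks": [
            {
                "network_id": n.network_id,
                "members": list(n.members),
                "n_contigs": n.n_contigs,
                "max_coverage": n.max_coverage,
                "mean_coverage": n.mean_coverage,
            }
            for n in partition.networks
        ],
        "singletons": sorted(partition.singletons),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return doc


def partition_from_json(doc: dict | str) -> NetworkPartition:
    if isinstance(doc, str):
        with open(doc) as fh:
            doc = json.load(fh)
    networks = [
        Network(
            d["network_id"],
            tuple(d["members"]),
            d["n_contigs"],
            d["max_coverage"],
            d["mean_coverage"],
        )
        for d in doc["networks"]
    ]
    return NetworkPartition(networks, frozenset(doc["singletons"]))
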