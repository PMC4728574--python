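"""Rank-structured viral taxonomy with lowest-common-ancestor queries.

The taxonomy backing network assignment mixes formal ICTV ranks (order,
family, subfamily, genus, species) with informal group labels such as
"ssDNA viruses" or "bacteria" that sit directly under the root, because
environmental virome annotations routinely resolve only to such groups.
Lineages may skip ranks (e.g. a species directly under a group); the LCA
operates on parent paths, not on rank slots.

A packaged ~40-node table (``default_taxonomy``) covers every label the
pipeline's synthetic communities and reports use.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .fileio import package_data_path

__all__ = [
    "RANK_ORDER",
    "TaxonNode",
    "TaxonomyTable",
    "TaxonomyError",
    "TaxonomyFormatError",
    "BrokenLineageError",
    "TaxonomyCycleError",
    "load_taxonomy",
    "lineage",
    "lca",
    "default_taxonomy",
]

#: Rank names from the root downward. Children must have a strictly lower
#: (later) rank than their parent; intermediate ranks may be absent.
RANK_ORDER: tuple[str, ...] = (
    "root",
    "group",
    "order",
    "family",
    "subfamily",
    "genus",
    "species",
)


class TaxonomyError(ValueError):
    """Base class for taxonomy-table validation failures."""


class TaxonomyFormatError(TaxonomyError):
    """Malformed table: bad columns, duplicate ids, unknown ranks."""


class BrokenLineageError(TaxonomyError):
    """A node's parent_id does not resolve to any node in the table."""


class TaxonomyCycleError(TaxonomyError):
    """Following parent links from some node never reaches the root."""


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    name: str
    rank: str
    parent_id: str | None  # None only for the root


@dataclass
class TaxonomyTable:
    """Validated collection of :class:`TaxonNode` keyed by taxon_id."""

    nodes: dict[str, TaxonNode]
    rank_order: tuple[str, ...] = RANK_ORDER
    _root: str = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._root = self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> str:
        ranks = {r: i for i, r in enumerate(self.rank_order)}
        roots = [t for t, n in self.nodes.items() if n.parent_id is None]
        if len(roots) != 1:
            raise TaxonomyFormatError(f"expected exactly one root, found {len(roots)}")
        root = roots[0]
        if self.nodes[root].rank != self.rank_order[0]:
            raise TaxonomyFormatError(f"root node {root!r} has rank {self.nodes[root].rank!r}")
        for tid, node in self.nodes.items():
            if node.rank not in ranks:
                raise TaxonomyFormatError(f"node {tid!r} has unknown rank {node.rank!r}")
            if node.parent_id is None:
                continue
            if node.parent_id == tid:
                raise TaxonomyCycleError(f"node {tid!r} is its own parent")
            parent = self.nodes.get(node.parent_id)
            if parent is None:
                raise BrokenLineageError(f"node {tid!r} has missing parent {node.parent_id!r}")
            if ranks[node.rank] <= ranks[parent.rank]:
                raise TaxonomyFormatError(
                    f"rank of {tid!r} ({node.rank}) not below parent {parent.taxon_id!r} ({parent.rank})"
                )
        # Strictly decreasing ranks already exclude cycles, but walk anyway so
        # the lineage-length invariant (<= |rank_order| steps) is enforced.
        for tid in self.nodes:
            steps, cur = 0, tid
            while self.nodes[cur].parent_id is not None:
                cur = self.nodes[cur].parent_id  # type: ignore[assignment]
                steps += 1
                if steps > len(self.rank_order):
                    raise TaxonomyCycleError(f"lineage of {tid!r} does not terminate at root")
        return root

    # -- queries ----------------------------------------------------------
    @property
    def root(self) -> str:
        return self._root

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def name(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].name

    def rank(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].rank

    def lineage(self, taxon_id: str) -> list[str]:
        """Taxon ids from the root down to ``taxon_id`` (inclusive)."""
        if taxon_id not in self.nodes:
            raise KeyError(f"unknown taxon_id {taxon_id!r}")
        path = [taxon_id]
        while self.nodes[path[-1]].parent_id is not None:
            path.append(self.nodes[path[-1]].parent_id)  # type: ignore[arg-type]
        return path[::-1]

    def depth(self, taxon_id: str) -> int:
        return len(self.lineage(taxon_id)) - 1

    def lca(self, taxon_ids: Iterable[str]) -> str:
        """Deepest node lying on every input lineage.

        Commutative and associative; ``lca({t}) == t``; taxa sharing only
        the root give the root.
        """
        ids = list(taxon_ids)
        if not ids:
            raise ValueError("lca() requires a non-empty set of taxon ids")
        paths = [self.lineage(t) for t in ids]
        common = paths[0]
        for p in paths[1:]:
            n = 0
            for a, b in zip(common, p):
                if a != b:
                    break
                n += 1
            common = common[:n]
        return common[-1]

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        """True if ``ancestor`` is on the lineage of ``descendant`` (or equal)."""
        return ancestor in self.lineage(descendant)

    def at_rank(self, rank: str) -> list[str]:
        if rank not in self.rank_order:
            raise ValueError(f"unknown rank {rank!r}")
        return sorted(t for t, n in self.nodes.items() if n.rank == rank)

    def species_under(self, ancestor: str, rank: str = "species") -> list[str]:
        """All ``rank``-level taxa whose lineage passes through ``ancestor``."""
        return [t for t in self.at_rank(rank) if ancestor in self.lineage(t)]


def load_taxonomy(path: str, rank_order: tuple[str, ...] = RANK_ORDER) -> TaxonomyTable:
    """Load and validate a taxonomy from TSV.

    Expected columns: taxon_id, name, rank, parent_id (root's parent empty).
    """
    nodes: dict[str, TaxonNode] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"taxon_id", "name", "rank", "parent_id"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TaxonomyFormatError(
                f"taxonomy TSV must have columns {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            tid = row["taxon_id"].strip()
            if not tid:
                continue
            if tid in nodes:
                raise TaxonomyFormatError(f"duplicate taxon_id {tid!r}")
            parent = (row.get("parent_id") or "").strip() or None
            nodes[tid] = TaxonNode(tid, row["name"].strip(), row["rank"].strip(), parent)
    return TaxonomyTable(nodes, rank_order)


def lineage(tax: TaxonomyTable, taxon_id: str) -> list[str]:
    """Functional alias for :meth:`TaxonomyTable.lineage`."""
    return tax.lineage(taxon_id)


def lca(tax: TaxonomyTable, taxon_ids: Iterable[str]) -> str:
    """Functional alias for :meth:`TaxonomyTable.lca`."""
    return tax.lca(taxon_ids)


def default_taxonomy() -> TaxonomyTable:
    """The packaged mixed-rank viral taxonomy used throughout the pipeline."""
    return load_taxonomy(package_data_path("taxonomy.tsv"))
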