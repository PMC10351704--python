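"""Rooted, ranked taxonomy tree with LCA queries.

The tree uses a fixed eight-rank hierarchy (root, domain, phylum, class,
order, family, genus, species). All taxonomic bookkeeping in the package —
reference lineages, weighted-LCA binning, rank profiles — goes through this
container.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

RANKS = ("root", "domain", "phylum", "class", "order", "family", "genus", "species")
RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}

#: Sentinel for queries that could not be placed anywhere on the tree.
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    parent_id: str | None
    rank: str
    name: str


class TaxonomyError(ValueError):
    """Raised for malformed trees or unresolvable taxa."""


class TaxonomyTree:
    """Immutable rooted taxonomy with parent pointers.

    Invariants enforced at construction: exactly one root, acyclic parent
    pointers, every non-root parent exists, and rank strictly deepens along
    every root-to-leaf path.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self._nodes:
                raise TaxonomyError(f"duplicate taxon_id {node.taxon_id!r}")
            if node.rank not in RANK_DEPTH:
                raise TaxonomyError(f"unknown rank {node.rank!r} for {node.taxon_id!r}")
            self._nodes[node.taxon_id] = node
        roots = [n for n in self._nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self._root = roots[0]
        if self._root.rank != "root":
            raise TaxonomyError("root node must have rank 'root'")
        self._children: dict[str, list[str]] = {tid: [] for tid in self._nodes}
        for node in self._nodes.values():
            if node.parent_id is None:
                continue
            parent = self._nodes.get(node.parent_id)
            if parent is None:
                raise TaxonomyError(
                    f"parent {node.parent_id!r} of {node.taxon_id!r} not in tree"
                )
            if RANK_DEPTH[node.rank] <= RANK_DEPTH[parent.rank]:
                raise TaxonomyError(
                    f"rank of {node.taxon_id!r} ({node.rank}) not deeper than "
                    f"parent rank ({parent.rank})"
                )
            self._children[parent.taxon_id].append(node.taxon_id)
        # rank monotonicity along parent pointers rules out cycles except for
        # self-consistent loops, which the single-root + parent-exists checks
        # already exclude; verify reachability anyway.
        seen = set()
        stack = [self._root.taxon_id]
        while stack:
            tid = stack.pop()
            seen.add(tid)
            stack.extend(self._children[tid])
        if seen != set(self._nodes):
            raise TaxonomyError("tree contains nodes unreachable from the root")

    # -- basic queries ----------------------------------------------------

    @property
    def root(self) -> TaxonNode:
        return self._root

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __iter__(self) -> Iterator[TaxonNode]:
        return iter(self._nodes.values())

    def node(self, taxon_id: str) -> TaxonNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxon {taxon_id!r}") from None

    def rank(self, taxon_id: str) -> str:
        return self.node(taxon_id).rank

    def parent(self, taxon_id: str) -> str | None:
        return self.node(taxon_id).parent_id

    def children(self, taxon_id: str) -> tuple[str, ...]:
        self.node(taxon_id)
        return tuple(self._children[taxon_id])

    def lineage(self, taxon_id: str) -> list[str]:
        """Taxon ids from the root down to (and including) ``taxon_id``."""
        path = []
        cur: str | None = taxon_id
        while cur is not None:
            path.append(cur)
            cur = self.node(cur).parent_id
        path.reverse()
        return path

    def depth(self, taxon_id: str) -> int:
        return len(self.lineage(taxon_id)) - 1

    def ancestor_at(self, taxon_id: str, rank: str) -> str | None:
        """Ancestor (or self) of ``taxon_id`` at ``rank``; None if the
        lineage never reaches that rank (assignment shallower than rank)."""
        if rank not in RANK_DEPTH:
            raise TaxonomyError(f"unknown rank {rank!r}")
        for tid in self.lineage(taxon_id):
            if self.node(tid).rank == rank:
                return tid
        return None

    def lca(self, *taxon_ids: str) -> str:
        if not taxon_ids:
            raise TaxonomyError("lca() of an empty set")
        common = self.lineage(taxon_ids[0])
        for tid in taxon_ids[1:]:
            other = set(self.lineage(tid))
            common = [t for t in common if t in other]
        return common[-1]

    def leaves(self, rank: str = "species") -> list[str]:
        return [n.taxon_id for n in self._nodes.values() if n.rank == rank]

    def subtree(self, taxon_id: str) -> set[str]:
        """All taxon ids at or below ``taxon_id``."""
        out = set()
        stack = [taxon_id]
        while stack:
            tid = stack.pop()
            out.add(tid)
            stack.extend(self._children[tid])
        return out

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_id\tparent_id\trank\tname\n")
            for node in self._nodes.values():
                fh.write(
                    f"{node.taxon_id}\t{node.parent_id or ''}\t{node.rank}\t{node.name}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        nodes = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("taxon_id"):
                raise TaxonomyError(f"{path}: missing taxonomy header line")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                taxon_id, parent_id, rank, name = line.split("\t")
                nodes.append(TaxonNode(taxon_id, parent_id or None, rank, name))
        return cls(nodes)

    def to_newick(self) -> str:
        def render(tid: str) -> str:
            kids = self._children[tid]
            label = self._nodes[tid].taxon_id
            if not kids:
                return label
            return "(" + ",".join(render(k) for k in kids) + ")" + label

        return render(self._root.taxon_id) + ";"
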