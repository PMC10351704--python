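"""Weighted-LCA taxonomic binning of homolog sequences.

Each query's homology hits against a reference set vote for their subject
lineages with weight equal to the hit bit score. After restricting to hits
within ``top_percent`` of the best bit score, the query is assigned to the
deepest taxonomy node whose subtree accumulates at least ``weight_threshold``
of the total retained weight (the root always qualifies). Depth-corrected
copy weights then aggregate assignments into per-rank taxonomic profiles,
and a consensus operation merges the gene-wise assignment with an externally
supplied composition-based scaffold label by taking their LCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .taxtree import RANK_DEPTH, UNASSIGNED, TaxonomyError, TaxonomyTree


@dataclass(frozen=True)
class ReferenceHit:
    query_id: str
    subject_id: str
    subject_taxon: str
    bit_score: float
    percent_identity: float = 0.0
    coverage: float = 0.0

    def __post_init__(self):
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be in [0, 100]")


@dataclass
class TaxonomicProfile:
    """Corrected abundance per taxon at one rank, plus the mass assigned
    above the rank and the unassigned mass. Conserves total copy weight."""

    sample_id: str
    rank: str
    taxa: dict[str, float] = field(default_factory=dict)
    above_rank: float = 0.0
    unassigned: float = 0.0

    @property
    def total(self) -> float:
        return sum(self.taxa.values()) + self.above_rank + self.unassigned


def weighted_lca(
    hits: Iterable[ReferenceHit],
    tree: TaxonomyTree,
    top_percent: float = 10.0,
    weight_threshold: float = 0.8,
) -> str:
    """Deepest taxon whose subtree holds >= ``weight_threshold`` of the
    bit-score weight of the retained (top-percent) hits.

    Returns the ``unassigned`` sentinel for an empty hit list. With a
    threshold > 0.5 the qualifying nodes form a single root-to-node chain,
    so the deepest one is unique.
    """
    hits = list(hits)
    if not hits:
        return UNASSIGNED
    if not 0.0 < weight_threshold <= 1.0:
        raise ValueError("weight_threshold must be in (0, 1]")
    best = max(h.bit_score for h in hits)
    retained = [h for h in hits if h.bit_score >= (1.0 - top_percent / 100.0) * best]
    total = sum(h.bit_score for h in retained)
    if total <= 0:
        return tree.root.taxon_id
    node_weight: dict[str, float] = {}
    for h in retained:
        for tid in tree.lineage(h.subject_taxon):
            node_weight[tid] = node_weight.get(tid, 0.0) + h.bit_score
    qualifying = [
        tid for tid, w in node_weight.items() if w >= weight_threshold * total - 1e-12
    ]
    # deepest; ties (possible only at threshold <= 0.5) broken by weight
    # then lexicographic id for determinism
    return max(qualifying, key=lambda t: (tree.depth(t), node_weight[t], t))


def assign_queries(
    hits_by_query: Mapping[str, Iterable[ReferenceHit]],
    tree: TaxonomyTree,
    top_percent: float = 10.0,
    weight_threshold: float = 0.8,
) -> dict[str, str]:
    return {
        q: weighted_lca(h, tree, top_percent, weight_threshold)
        for q, h in hits_by_query.items()
    }


def profile_at_rank(
    assignments: Mapping[str, str],
    copy_weights: Mapping[str, float],
    tree: TaxonomyTree,
    rank: str,
    sample_id: str = "sample",
) -> TaxonomicProfile:
    """Aggregate per-query copy weights (1.0 unassembled, scaffold depth
    assembled) at the given rank.

    A query assigned below ``rank`` accrues to its ancestor at that rank; a
    query assigned above it accrues to the ``above_rank`` mass; unassigned
    queries keep their own bucket. Total mass is conserved.
    """
    if rank not in RANK_DEPTH:
        raise TaxonomyError(f"unknown rank {rank!r}")
    profile = TaxonomicProfile(sample_id, rank)
    for query, taxon in assignments.items():
        w = float(copy_weights[query])
        if taxon == UNASSIGNED:
            profile.unassigned += w
            continue
        at_rank = tree.ancestor_at(taxon, rank)
        if at_rank is None:
            profile.above_rank += w
        else:
            profile.taxa[at_rank] = profile.taxa.get(at_rank, 0.0) + w
    return profile


def consensus_bin(
    gene_wise_taxon: str, composition_taxon: str, tree: TaxonomyTree
) -> str:
    """Consensus of a gene-wise (homology) assignment and a composition-based
    scaffold assignment: their LCA; if either is unassigned, the other."""
    if gene_wise_taxon == UNASSIGNED:
        return composition_taxon
    if composition_taxon == UNASSIGNED:
        return gene_wise_taxon
    return tree.lca(gene_wise_taxon, composition_taxon)
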