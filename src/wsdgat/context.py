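"""Gene-neighborhood profiling of marker hits on annotated scaffolds.

For each marker gene the window of up to N genes on either side (ordered by
coordinate) is extracted, and the presence of configured lipid-metabolism
domains — AGPAT (PF01553), HAD-like hydrolase (PF12710), acyl-CoA synthase
(PF00501/PF13193), SCP-2 (PF02036) — is flagged, summarizing how often the
conserved neutral-lipid gene arrangement accompanies the marker. A
multiset-Jaccard domain-content similarity serves as a lightweight stand-in
for nucleotide-level synteny comparison between scaffolds.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import ScaffoldRecord

logger = logging.getLogger(__name__)

#: Lipid-metabolism domains of interest flagged in marker neighborhoods.
DEFAULT_CONTEXT_DOMAINS = ("PF01553", "PF12710", "PF00501", "PF13193", "PF02036")


@dataclass
class ContextProfile:
    marker_gene_id: str
    scaffold_id: str
    #: (gene_id, strand, offset_in_genes, domain_ids); marker at offset 0,
    #: offsets contiguous within the window.
    window: list[tuple[str, str, int, tuple[str, ...]]]
    flags: dict[str, bool]


def extract_context(
    scaffold: ScaffoldRecord,
    marker_gene_id: str,
    window_genes: int = 10,
    domains_of_interest: Sequence[str] = DEFAULT_CONTEXT_DOMAINS,
) -> ContextProfile:
    """Window of up to ``window_genes`` genes on each side of the marker,
    in coordinate order, with domain-of-interest flags over the window
    (marker gene excluded from the flag scan)."""
    order = sorted(scaffold.genes, key=lambda g: (g.start, g.gene_id))
    try:
        pos = next(i for i, g in enumerate(order) if g.gene_id == marker_gene_id)
    except StopIteration:
        raise ValueError(
            f"marker gene {marker_gene_id!r} not on scaffold {scaffold.scaffold_id!r}"
        ) from None
    lo = max(0, pos - window_genes)
    hi = min(len(order), pos + window_genes + 1)
    window = [
        (g.gene_id, g.strand, i - pos, tuple(g.domain_ids))
        for i, g in enumerate(order[lo:hi], start=lo)
    ]
    neighborhood_domains = {
        d for g in order[lo:hi] if g.gene_id != marker_gene_id for d in g.domain_ids
    }
    flags = {d: d in neighborhood_domains for d in domains_of_interest}
    return ContextProfile(marker_gene_id, scaffold.scaffold_id, window, flags)


def cooccurrence_summary(
    profiles: Iterable[ContextProfile], domain_set: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-domain presence counts and fractions over marker contexts."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no context profiles")
    if domain_set is None:
        domain_set = DEFAULT_CONTEXT_DOMAINS
    if not domain_set:
        raise ValueError("empty domain set")
    rows = []
    for d in domain_set:
        n = sum(1 for p in profiles if p.flags.get(d, False))
        rows.append({"domain": d, "n_contexts_present": n,
                     "fraction": n / len(profiles)})
    return pd.DataFrame(rows)


def domain_content_similarity(
    scaffold_a: ScaffoldRecord, scaffold_b: ScaffoldRecord
) -> float:
    """Jaccard index of the domain-id multisets of two scaffolds' genes —
    a domain-content stand-in for nucleotide synteny identity."""
    ca = Counter(d for g in scaffold_a.genes for d in g.domain_ids)
    cb = Counter(d for g in scaffold_b.genes for d in g.domain_ids)
    if not ca or not cb:
        for sc, c in ((scaffold_a, ca), (scaffold_b, cb)):
            if not c:
                logger.warning(
                    "scaffold %s has no annotated domains; similarity is 0",
                    sc.scaffold_id,
                )
        return 0.0
    inter = sum((ca & cb).values())
    union = sum((ca | cb).values())
    return inter / union if union else 0.0
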