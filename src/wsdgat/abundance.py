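"""Depth-corrected gene-copy estimation and single-copy normalization.

Estimated gene copies in a metagenome sample combine the two assembly
fractions: every identified sequence from the unassembled fraction counts
1.0, and every identified gene on an assembled scaffold counts that
scaffold's read depth (the copies lost by assembly collapse). The family's
estimated copies are then normalized against a panel of 12 single-copy
ribosomal-protein genes, yielding copies-per-genome units; the spread of the
12 ratios (sd, CV) measures the internal consistency of the normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .search import DomainHit
from .taxtree import TaxonomyTree

logger = logging.getLogger(__name__)


class AbundanceError(ValueError):
    pass


@dataclass(frozen=True)
class RatioSummary:
    """Family abundance normalized by each panel gene: per-gene ratios and
    their mean, sd (n-1 denominator) and coefficient of variation."""

    ratios: dict[str, float]
    mean: float
    sd: float
    cv: float


@dataclass(frozen=True)
class AbundanceEstimate:
    sample_id: str
    family_id: str
    copies_unassembled: float
    copies_assembled_weighted: float
    panel: RatioSummary | None = None

    @property
    def estimated_copies(self) -> float:
        return self.copies_unassembled + self.copies_assembled_weighted


def _hits_frame(hits) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        return hits
    rows = [{"protein_id": h.protein_id, "domain_id": h.domain_id} for h in hits]
    return pd.DataFrame(rows, columns=["protein_id", "domain_id"])


def estimate_copies(
    hits: Iterable[DomainHit] | pd.DataFrame,
    scaffolds: pd.DataFrame | Mapping[str, float],
    fractions: pd.DataFrame | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Depth-corrected estimated copies per sample per domain.

    Parameters
    ----------
    hits:
        Domain hits (objects or a DataFrame with at least ``protein_id`` and
        ``domain_id``).
    scaffolds:
        Scaffold depth table (``scaffold_id``, ``read_depth``[, ``sample_id``])
        or a plain ``{scaffold_id: read_depth}`` mapping.
    fractions:
        Per-protein fraction labels: ``protein_id``, ``sample_id``,
        ``scaffold_id`` (empty/NaN for the unassembled fraction). When
        omitted, the scaffold is inferred from the ``<scaffold>_<ordinal>``
        protein naming convention and the sample defaults to a single
        unnamed sample.
    strict:
        An assembled hit whose scaffold has no depth raises in strict mode;
        in lenient mode it contributes 1.0 with a warning.

    Returns
    -------
    DataFrame with one row per (sample_id, domain_id):
    ``copies_unassembled``, ``copies_assembled_weighted``,
    ``estimated_copies``.
    """
    df = _hits_frame(hits).copy()
    if df.empty:
        return pd.DataFrame(
            columns=["sample_id", "domain_id", "copies_unassembled",
                     "copies_assembled_weighted", "estimated_copies"]
        )
    if isinstance(scaffolds, pd.DataFrame):
        depth_of = dict(zip(scaffolds["scaffold_id"], scaffolds["read_depth"]))
    else:
        depth_of = dict(scaffolds)

    if fractions is not None:
        meta = fractions.set_index("protein_id")
        df["scaffold_id"] = df["protein_id"].map(meta["scaffold_id"]).fillna("")
        if "sample_id" in meta.columns:
            df["sample_id"] = df["protein_id"].map(meta["sample_id"])
    else:
        def infer_scaffold(pid: str) -> str:
            stem = pid.rsplit("_", 1)[0]
            return stem if stem in depth_of else ""

        df["scaffold_id"] = df["protein_id"].map(infer_scaffold)
    if "sample_id" not in df.columns:
        df["sample_id"] = "sample"

    weights = np.ones(len(df))
    assembled = df["scaffold_id"].astype(str) != ""
    for i in np.flatnonzero(assembled.to_numpy()):
        sid = df["scaffold_id"].iat[i]
        depth = depth_of.get(sid)
        if depth is None:
            msg = (f"assembled hit {df['protein_id'].iat[i]!r} references "
                   f"scaffold {sid!r} with no depth")
            if strict:
                raise AbundanceError(msg)
            logger.warning("%s; counting as 1.0", msg)
            weights[i] = 1.0
        else:
            weights[i] = float(depth)
    df["weight"] = weights
    df["assembled"] = assembled

    out = (
        df.groupby(["sample_id", "domain_id"], sort=True)
        .apply(
            lambda g: pd.Series(
                {
                    "copies_unassembled": float(g.loc[~g["assembled"], "weight"].sum()),
                    "copies_assembled_weighted": float(
                        g.loc[g["assembled"], "weight"].sum()
                    ),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    out["estimated_copies"] = (
        out["copies_unassembled"] + out["copies_assembled_weighted"]
    )
    return out


def single_copy_ratios(
    family_estimate: float, panel_estimates: Mapping[str, float]
) -> RatioSummary:
    """Ratio of the family estimate to each single-copy panel gene estimate,
    with the mean/sd/CV of the per-gene ratios."""
    if not panel_estimates:
        raise AbundanceError("empty single-copy panel")
    for gene, est in panel_estimates.items():
        if est <= 0:
            raise AbundanceError(
                f"panel gene {gene!r} has non-positive estimated copies ({est})"
            )
    ratios = {g: family_estimate / est for g, est in panel_estimates.items()}
    values = np.array(list(ratios.values()))
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    cv = sd / mean if mean != 0 else math.inf
    return RatioSummary(ratios, mean, sd, cv)


def abundance_for_sample(
    estimates: pd.DataFrame,
    sample_id: str,
    family_domain: str,
    panel_domains: Mapping[str, str],
) -> AbundanceEstimate:
    """Assemble the family estimate plus the 12-ratio normalization summary
    for one sample from an :func:`estimate_copies` table."""
    sub = estimates[estimates["sample_id"] == sample_id].set_index("domain_id")

    def est(domain: str) -> tuple[float, float]:
        if domain not in sub.index:
            return 0.0, 0.0
        row = sub.loc[domain]
        return float(row["copies_unassembled"]), float(row["copies_assembled_weighted"])

    fam_u, fam_a = est(family_domain)
    panel_est = {
        gene: float(sub.loc[dom, "estimated_copies"]) if dom in sub.index else 0.0
        for gene, dom in panel_domains.items()
    }
    summary = single_copy_ratios(fam_u + fam_a, panel_est)
    return AbundanceEstimate(sample_id, family_domain, fam_u, fam_a, summary)


def genome_census(
    per_genome_hits: Mapping[str, int] | pd.DataFrame,
    taxa: Mapping[str, str] | None = None,
    tree: TaxonomyTree | None = None,
    rank: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Exact per-genome family copy counts and optional per-taxon summary.

    ``per_genome_hits`` maps genome -> copy count (or a DataFrame with
    ``genome_id``/``n_copies``[, ``taxon_id``]); genomes with zero copies
    must be included — they enter the denominator of "fraction of genomes
    with >= 1 homolog". The optional summary aggregates at ``rank`` using
    the taxonomy tree, reporting the carrier fraction and the mean copy
    number among carriers.
    """
    if isinstance(per_genome_hits, pd.DataFrame):
        census = per_genome_hits.copy()
    else:
        census = pd.DataFrame(
            {"genome_id": list(per_genome_hits), "n_copies": list(per_genome_hits.values())}
        )
    if taxa is not None:
        census["taxon_id"] = census["genome_id"].map(dict(taxa))
        if census["taxon_id"].isna().any():
            bad = census.loc[census["taxon_id"].isna(), "genome_id"].tolist()
            raise AbundanceError(f"genomes with unknown taxon label: {bad[:3]}")
    summary = None
    if rank is not None:
        if tree is None or "taxon_id" not in census.columns:
            raise AbundanceError("per-taxon summary needs a tree and taxon labels")
        for t in census["taxon_id"]:
            tree.node(t)  # raises on unknown taxa
        census["_group"] = [tree.ancestor_at(t, rank) for t in census["taxon_id"]]
        summary = (
            census.groupby("_group")
            .apply(
                lambda g: pd.Series(
                    {
                        "n_genomes": len(g),
                        "fraction_with_family": float((g["n_copies"] >= 1).mean()),
                        "mean_copies_carriers": (
                            float(g.loc[g["n_copies"] >= 1, "n_copies"].mean())
                            if (g["n_copies"] >= 1).any()
                            else 0.0
                        ),
                        "max_copies": int(g["n_copies"].max()),
                    }
                ),
                include_groups=False,
            )
            .reset_index()
            .rename(columns={"_group": rank})
        )
        census = census.drop(columns="_group")
    return census, summary
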