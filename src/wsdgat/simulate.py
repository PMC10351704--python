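"""Synthetic metagenomes with planted WS/DGAT-like gene content.

This module generates taxonomically structured communities whose genomes
carry known copy numbers of a marker protein family (the wax-ester
synthase / DGAT acyltransferase domain family in the default configuration)
and exactly one copy of each of 12 single-copy ribosomal-protein genes. It
emits the artifacts a real metagenome analysis starts from — protein FASTA
for the assembled and unassembled fractions, GFF3 gene models, per-scaffold
read depths — together with ground-truth tables, so every downstream stage
of the pipeline is testable without external data.

Model summary
-------------
* Taxonomy: a balanced ranked tree (root/domain/phylum/.../species).
* Copy numbers: zero-inflated, zero-truncated Poisson — a species carries
  the family with probability ``prevalence``; carriers draw their paralog
  count from a zero-truncated Poisson with mean parameter ``mean_copies``.
* Sequences: i.i.d. substitutions (no indels) along root-to-leaf branches,
  each mutated site replaced by a uniformly random alternative residue, so
  expected pairwise identity is an analytic function of path length.
* Communities: per-group log-normal abundance profiles with per-sample
  jitter; genome coverage is log-normal around ``depth_scale`` scaled by
  relative abundance.
* Emission: each gene copy is assembled (probability ``assembly_fraction``,
  landing on a scaffold whose read depth equals the genome coverage) or
  unassembled (emitting Poisson(coverage) single protein records).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import Gene, ScaffoldRecord, write_depth_tsv, write_gff3
from .taxtree import RANKS, TaxonNode, TaxonomyTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Robinson & Robinson amino-acid background frequencies, normalized.
_BG = {
    "A": 0.0780, "C": 0.0192, "D": 0.0536, "E": 0.0624, "F": 0.0387,
    "G": 0.0738, "H": 0.0219, "I": 0.0514, "K": 0.0574, "L": 0.0901,
    "M": 0.0224, "N": 0.0448, "P": 0.0520, "Q": 0.0426, "R": 0.0512,
    "S": 0.0712, "T": 0.0584, "V": 0.0647, "W": 0.0132, "Y": 0.0321,
}
BACKGROUND = np.array([_BG[a] for a in AMINO_ACIDS])
BACKGROUND /= BACKGROUND.sum()

FAMILY_DOMAIN = "PF03007"

#: 12 single-copy ribosomal-protein marker genes (gene -> Pfam domain).
DEFAULT_PANEL = {
    "rplB": "PF00181", "rplC": "PF00297", "rplD": "PF00573", "rplE": "PF00281",
    "rplF": "PF00347", "rplN": "PF00238", "rplP": "PF00252", "rpsC": "PF00189",
    "rpsE": "PF00333", "rpsH": "PF00410", "rpsK": "PF00411", "rpsS": "PF00203",
}

#: Lipid-metabolism neighborhood domains planted next to marker genes:
#: AGPAT (PF01553), HAD-like hydrolase (PF12710), acyl-CoA synthase
#: (PF00501 + PF13193).
CONTEXT_NEIGHBOR_DOMAINS = (
    ("PF01553", "PF12710"),  # AGPAT-HAD fusion
    ("PF00501", "PF13193"),  # acyl-CoA synthase
    ("PF01553",),            # typical AGPAT
)

#: Fixed 100-residue seed for the marker family's ancestral domain sequence.
DEFAULT_SEED_PROTEIN = (
    "MTPLNPMDQLFLWLEKRQQPMHVGGLQLFSFPEGAGPKYVSELAQQMRDYCHPVAPFNQR"
    "LTRRLGQYYWTRDKQFDIDHHFRHEALPKPGRIRELLS"
)


def seq_to_ints(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-standard amino acid {exc.args[0]!r}") from None


def ints_to_seq(arr: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in arr)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return ints_to_seq(rng.choice(20, size=length, p=BACKGROUND))


# ---------------------------------------------------------------------------
# Taxonomy construction
# ---------------------------------------------------------------------------

def build_taxonomy(
    seed: int,
    n_phyla: int,
    children_per_node: int,
    species_per_genus: int | None = None,
) -> TaxonomyTree:
    """Balanced ranked taxonomy: one domain, ``n_phyla`` phyla, then
    ``children_per_node`` children per node down to the species rank
    (``species_per_genus`` overrides the fanout of the last split).

    Deterministic for fixed arguments (``seed`` is recorded for API symmetry
    with the stochastic generators).
    """
    if n_phyla < 1 or children_per_node < 1:
        raise ValueError("n_phyla and children_per_node must be >= 1")
    if species_per_genus is not None and species_per_genus < 1:
        raise ValueError("species_per_genus must be >= 1")
    nodes = [TaxonNode("root", None, "root", "root"),
             TaxonNode("d1", "root", "domain", "Bacteria")]
    frontier = ["d1"]
    for rank in RANKS[2:]:
        if rank == "phylum":
            fanout = n_phyla
        elif rank == "species" and species_per_genus is not None:
            fanout = species_per_genus
        else:
            fanout = children_per_node
        new_frontier = []
        for parent in frontier:
            for i in range(1, fanout + 1):
                tid = f"{parent}.{rank[0]}{i}"
                nodes.append(TaxonNode(tid, parent, rank, tid))
                new_frontier.append(tid)
        frontier = new_frontier
    return TaxonomyTree(nodes)


# ---------------------------------------------------------------------------
# Genomes and copy numbers
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberModel:
    """Zero-inflated zero-truncated-Poisson copy-number model.

    A genome carries >= 1 family copy with probability ``prevalence``;
    carriers draw from ZTP(``mean_copies``). ``per_phylum`` overrides the
    (prevalence, mean_copies) pair for the subtree of a named phylum,
    mirroring the strong phylum dependence of the family in genome censuses.
    """

    prevalence: float = 0.35
    mean_copies: float = 2.5
    per_phylum: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.mean_copies <= 0:
            raise ValueError("mean_copies must be > 0")

    def params_for(self, tree: TaxonomyTree, taxon_id: str) -> tuple[float, float]:
        phylum = tree.ancestor_at(taxon_id, "phylum")
        if phylum is not None and phylum in self.per_phylum:
            return self.per_phylum[phylum]
        return self.prevalence, self.mean_copies


def ztp_mean(lam: float) -> float:
    """Mean of the zero-truncated Poisson with rate ``lam``."""
    return lam / (1.0 - np.exp(-lam))


def expected_copies_per_genome(model: CopyNumberModel) -> float:
    """Marginal expected family copies per genome under the default params."""
    return model.prevalence * ztp_mean(model.mean_copies)


def _sample_ztp(rng: np.random.Generator, lam: float) -> int:
    # inverse-CDF draw on the truncated support; exact and O(k) even for
    # tiny rates, where rejection sampling would almost never accept
    p0 = np.exp(-lam)
    u = rng.uniform(p0, 1.0)
    k, term, cdf = 0, p0, p0
    while cdf < u:
        k += 1
        term *= lam / k
        cdf += term
    return max(k, 1)


@dataclass
class SyntheticGenome:
    genome_id: str
    taxon_id: str
    family_copy_count: int
    panel_genes: tuple[str, ...] = tuple(DEFAULT_PANEL)
    family_protein_seqs: list[str] = field(default_factory=list)


def simulate_genomes(
    tree: TaxonomyTree,
    copy_model: CopyNumberModel | None = None,
    seed: int = 0,
    genomes_per_species: int = 1,
) -> list[SyntheticGenome]:
    """One genome per species leaf (or ``genomes_per_species``), with planted
    family copy numbers and exactly one copy of each panel gene."""
    copy_model = copy_model or CopyNumberModel()
    species = sorted(tree.leaves("species"))
    if not species:
        raise ValueError("taxonomy has no species leaves")
    rng = np.random.default_rng(seed)
    genomes = []
    for sp in species:
        p, lam = copy_model.params_for(tree, sp)
        for j in range(genomes_per_species):
            n = _sample_ztp(rng, lam) if rng.random() < p else 0
            gid = f"G_{sp}" if genomes_per_species == 1 else f"G_{sp}_{j + 1}"
            genomes.append(SyntheticGenome(gid, sp, n))
    return genomes


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if hit.size:
        # uniform over the 19 alternative residues
        out[hit] = (out[hit] + rng.integers(1, 20, size=hit.size)) % 20
    return out


def leaf_sequences(
    seed_protein: str, tree: TaxonomyTree, subs_per_site_per_branch: float, seed: int
) -> dict[str, str]:
    """Evolve the seed protein down every root-to-species path.

    Each branch applies i.i.d. substitutions at the given per-site rate, so
    two species whose paths diverge d branches ago have expected identity of
    roughly (1 - rate)^(2d) (plus a small chance-match term).
    """
    if not seed_protein:
        raise ValueError("seed protein must be non-empty")
    if len(seed_protein) < 50:
        raise ValueError("seed protein must be at least 50 residues")
    if subs_per_site_per_branch < 0:
        raise ValueError("substitution rate must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}

    def walk(taxon_id: str, seq: np.ndarray) -> None:
        node = tree.node(taxon_id)
        if node.rank == "species":
            out[taxon_id] = ints_to_seq(seq)
            return
        for child in sorted(tree.children(taxon_id)):
            walk(child, _mutate(rng, seq, subs_per_site_per_branch))

    walk(tree.root.taxon_id, seq_to_ints(seed_protein))
    return out


def evolve_family_sequences(
    seed_protein: str,
    tree: TaxonomyTree,
    genomes: list[SyntheticGenome],
    subs_per_site_per_branch: float,
    seed: int,
    paralog_rate: float = 0.02,
) -> dict[str, list[str]]:
    """Assign evolved family sequences to every genome's copies (in place).

    Paralogs within a genome diverge from the species sequence by one extra
    round of substitutions at ``paralog_rate``, keeping within-genome
    identity high relative to the clustering cutoff.
    """
    leaves = leaf_sequences(seed_protein, tree, subs_per_site_per_branch, seed)
    rng = np.random.default_rng(seed + 1)
    out: dict[str, list[str]] = {}
    for g in sorted(genomes, key=lambda g: g.genome_id):
        base = seq_to_ints(leaves[g.taxon_id])
        seqs = [ints_to_seq(_mutate(rng, base, paralog_rate))
                for _ in range(g.family_copy_count)]
        g.family_protein_seqs = seqs
        out[g.genome_id] = seqs
    return out


# ---------------------------------------------------------------------------
# Community design and metagenome emission
# ---------------------------------------------------------------------------

@dataclass
class CommunityDesign:
    sample_id: str
    group: str
    abundances: dict[str, float]  # genome_id -> relative abundance, sums to 1
    assembly_fraction: float = 0.7
    depth_scale: float = 10.0   # mean coverage of an evenly abundant genome
    depth_sigma: float = 0.5    # log-normal sd of coverage noise
    context_rate: float = 0.6   # chance an assembled marker gets lipid neighbors
    seed: int = 0

    def __post_init__(self):
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"sample {self.sample_id!r}: abundances sum to {total}, not 1"
            )
        if any(a < 0 for a in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        if not 0.0 <= self.assembly_fraction <= 1.0:
            raise ValueError("assembly_fraction must be in [0, 1]")


def design_communities(
    genomes: list[SyntheticGenome],
    seed: int,
    n_samples_per_group: int = 3,
    groups: tuple[str, ...] = ("ANT", "ARG"),
    group_effect: float = 1.0,
    sample_jitter: float = 0.3,
    **design_kwargs,
) -> list[CommunityDesign]:
    """Per-group log-normal abundance profiles with per-sample jitter.

    Each group draws its own log-abundance offset per genome (sd
    ``group_effect``), planting reproducible between-group community
    structure; samples within a group jitter around the group profile.
    """
    rng = np.random.default_rng(seed)
    gids = [g.genome_id for g in genomes]
    base = rng.normal(0.0, 1.0, size=len(gids))
    designs = []
    for gi, group in enumerate(groups):
        offset = rng.normal(0.0, group_effect, size=len(gids))
        for si in range(1, n_samples_per_group + 1):
            jitter = rng.normal(0.0, sample_jitter, size=len(gids))
            logab = base + offset + jitter
            ab = np.exp(logab)
            ab /= ab.sum()
            designs.append(
                CommunityDesign(
                    sample_id=f"{group}{si:02d}",
                    group=group,
                    abundances=dict(zip(gids, ab)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    **design_kwargs,
                )
            )
    return designs


@dataclass
class SampleData:
    """One simulated metagenome sample plus its ground truth.

    ``proteins`` has one row per emitted protein record with columns
    protein_id, sample_id, genome_id, taxon_id, gene, domain, fraction
    ("assembled"/"unassembled"), scaffold_id (empty if unassembled),
    weight (scaffold depth if assembled, 1.0 otherwise) and seq.
    """

    sample_id: str
    group: str
    design: CommunityDesign
    proteins: pd.DataFrame
    scaffolds: list[ScaffoldRecord]

    def truth_estimated_copies(self, gene: str = "family") -> float:
        sub = self.proteins[self.proteins["gene_class"] == gene]
        return float(sub["weight"].sum())

    def truth_panel_copies(self) -> dict[str, float]:
        return {g: self.truth_estimated_copies(g) for g in DEFAULT_PANEL}


def simulate_metagenome(
    genomes: list[SyntheticGenome],
    design: CommunityDesign,
    emit_sequences: bool = True,
    panel: dict[str, str] | None = None,
) -> SampleData:
    """Emit one sample's assembled/unassembled protein records, scaffolds
    with read depths, and an internally consistent truth table."""
    panel = panel or DEFAULT_PANEL
    missing = [g.genome_id for g in genomes if g.genome_id not in design.abundances]
    if missing:
        raise ValueError(f"design does not cover genomes: {missing[:3]}...")
    rng = np.random.default_rng(design.seed)
    n = len(genomes)
    rows: list[dict] = []
    scaffolds: list[ScaffoldRecord] = []
    u_counter = 0

    for g in sorted(genomes, key=lambda g: g.genome_id):
        ab = design.abundances[g.genome_id]
        coverage = (
            design.depth_scale * n * ab
            * rng.lognormal(-design.depth_sigma**2 / 2.0, design.depth_sigma)
        )
        if coverage <= 0:
            continue
        # gene roster: family copies then the single-copy panel
        roster: list[tuple[str, str, str]] = []  # (gene_class, domain, seq)
        for i, _ in enumerate(range(g.family_copy_count)):
            seq = (
                g.family_protein_seqs[i]
                if emit_sequences and g.family_protein_seqs
                else ""
            )
            roster.append(("family", FAMILY_DOMAIN, seq))
        for gene, dom in panel.items():
            seq = random_protein(rng, 120) if emit_sequences else ""
            roster.append((gene, dom, seq))

        assembled_mask = rng.random(len(roster)) < design.assembly_fraction
        scaffold_genes: list[tuple[str, str, str]] = []
        for (gene_class, dom, seq), asm in zip(roster, assembled_mask):
            if asm:
                scaffold_genes.append((gene_class, dom, seq))
            else:
                k = rng.poisson(coverage)
                for _ in range(k):
                    u_counter += 1
                    rows.append(
                        {
                            "protein_id": f"{design.sample_id}_U{u_counter}",
                            "sample_id": design.sample_id,
                            "genome_id": g.genome_id,
                            "taxon_id": g.taxon_id,
                            "gene_class": gene_class,
                            "domain": dom,
                            "fraction": "unassembled",
                            "scaffold_id": "",
                            "weight": 1.0,
                            "seq": seq,
                        }
                    )
        if not scaffold_genes:
            continue
        scaffold_id = f"{design.sample_id}_S{g.genome_id}"
        genes: list[Gene] = []
        cursor = 1
        ordinal = 0
        emitted: list[dict] = []

        def place(gene_class: str, domains: tuple[str, ...], seq: str) -> None:
            nonlocal cursor, ordinal
            ordinal += 1
            aa_len = len(seq) if seq else 120
            start, end = cursor, cursor + 3 * aa_len + 2
            cursor = end + 51
            pid = f"{scaffold_id}_{ordinal}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(pid, start, end, strand, domains))
            emitted.append(
                {
                    "protein_id": pid,
                    "sample_id": design.sample_id,
                    "genome_id": g.genome_id,
                    "taxon_id": g.taxon_id,
                    "gene_class": gene_class,
                    "domain": domains[0] if domains else "",
                    "fraction": "assembled",
                    "scaffold_id": scaffold_id,
                    "weight": float(coverage),
                    "seq": seq,
                }
            )

        for gene_class, dom, seq in scaffold_genes:
            if gene_class == "family" and rng.random() < design.context_rate:
                # plant the conserved lipid-gene arrangement around the marker
                place("context", CONTEXT_NEIGHBOR_DOMAINS[0],
                      random_protein(rng, 100) if emit_sequences else "")
                place(gene_class, (dom,), seq)
                place("context", CONTEXT_NEIGHBOR_DOMAINS[1],
                      random_protein(rng, 100) if emit_sequences else "")
                place("context", CONTEXT_NEIGHBOR_DOMAINS[2],
                      random_protein(rng, 100) if emit_sequences else "")
            else:
                place(gene_class, (dom,), seq)
        # a few filler genes without annotated domains
        for _ in range(int(rng.integers(1, 4))):
            place("filler", (), random_protein(rng, 80) if emit_sequences else "")

        # context/filler proteins are genomic background, not gene copies of
        # the tracked families; they carry the scaffold weight all the same.
        scaffolds.append(
            ScaffoldRecord(scaffold_id, design.sample_id, cursor + 100,
                           float(coverage), genes)
        )
        rows.extend(emitted)

    columns = ["protein_id", "sample_id", "genome_id", "taxon_id", "gene_class",
               "domain", "fraction", "scaffold_id", "weight", "seq"]
    proteins = pd.DataFrame(rows, columns=columns)
    return SampleData(design.sample_id, design.group, design, proteins, scaffolds)


# ---------------------------------------------------------------------------
# Whole-study convenience and file emission
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    tree: TaxonomyTree
    genomes: list[SyntheticGenome]
    designs: list[CommunityDesign]
    samples: list[SampleData]
    leaf_seqs: dict[str, str]
    seed: int

    @property
    def groups(self) -> dict[str, str]:
        return {s.sample_id: s.group for s in self.samples}

    def all_proteins(self) -> pd.DataFrame:
        return pd.concat([s.proteins for s in self.samples], ignore_index=True)

    def all_scaffolds(self) -> list[ScaffoldRecord]:
        return [sc for s in self.samples for sc in s.scaffolds]


def simulate_study(
    seed: int,
    n_phyla: int = 4,
    children_per_node: int = 2,
    copy_model: CopyNumberModel | None = None,
    subs_per_site_per_branch: float = 0.05,
    n_samples_per_group: int = 3,
    groups: tuple[str, ...] = ("ANT", "ARG"),
    emit_sequences: bool = True,
    **design_kwargs,
) -> StudyData:
    """Generate a full multi-sample, two-group study with ground truth.

    Defaults emulate the structure of a two-environment sediment comparison:
    two groups of replicate samples over a shared genome pool, a per-branch
    substitution rate of 0.05 (within-genus identity ~0.90, between-phylum
    ~0.55, bracketing the 0.8 clustering cutoff), and the copy-number model's
    defaults (prevalence 0.35, ZTP mean parameter 2.5, i.e. ~0.96 expected
    family copies per genome).
    """
    tree = build_taxonomy(seed, n_phyla=n_phyla, children_per_node=children_per_node)
    genomes = simulate_genomes(tree, copy_model, seed=seed)
    leaf_seqs = leaf_sequences(DEFAULT_SEED_PROTEIN, tree,
                               subs_per_site_per_branch, seed)
    if emit_sequences:
        evolve_family_sequences(DEFAULT_SEED_PROTEIN, tree, genomes,
                                subs_per_site_per_branch, seed)
    designs = design_communities(
        genomes, seed=seed + 7919, n_samples_per_group=n_samples_per_group,
        groups=groups, **design_kwargs,
    )
    samples = [simulate_metagenome(genomes, d, emit_sequences=emit_sequences)
               for d in designs]
    return StudyData(tree, genomes, designs, samples, leaf_seqs, seed)


def write_sample(sample: SampleData, outdir: str | Path) -> None:
    """Write one sample's FASTA (assembled/unassembled), GFF3, depth TSV,
    truth table and manifest under ``outdir``."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = sample.proteins
    for fraction in ("assembled", "unassembled"):
        recs = [
            SeqRecord(Seq(r.seq), id=r.protein_id, description="")
            for r in df[df["fraction"] == fraction].itertuples()
            if r.seq
        ]
        SeqIO.write(recs, outdir / f"proteins_{fraction}.faa", "fasta")
    write_gff3(sample.scaffolds, outdir / "genes.gff3")
    write_depth_tsv(sample.scaffolds, outdir / "depths.tsv")
    df.drop(columns="seq").to_csv(outdir / "truth_proteins.tsv", sep="\t", index=False)
    manifest = {
        "sample_id": sample.sample_id,
        "group": sample.group,
        "seed": sample.design.seed,
        "assembly_fraction": sample.design.assembly_fraction,
        "depth_scale": sample.design.depth_scale,
        "depth_sigma": sample.design.depth_sigma,
        "context_rate": sample.design.context_rate,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def make_reference(tree: TaxonomyTree, leaf_seqs: dict[str, str]) -> pd.DataFrame:
    """Reference protein set with lineages for LCA binning: one sequence per
    species leaf (subject_id, taxon_id, seq)."""
    rows = [
        {"subject_id": f"REF_{taxon}", "taxon_id": taxon, "seq": seq}
        for taxon, seq in sorted(leaf_seqs.items())
    ]
    return pd.DataFrame(rows)


def reference_hits(query_seq: str, reference: pd.DataFrame, top_n: int = 100):
    """Homology hits of a query against the synthetic reference by Hamming
    identity (the generator introduces no indels, so sequences align
    end-to-end). Bit score is 2 bits per identical residue."""
    from .taxonomy import ReferenceHit

    q = np.frombuffer(query_seq.encode(), dtype=np.uint8)
    same_len = reference[reference["seq"].str.len() == len(q)]
    if same_len.empty:
        return []
    mat = np.frombuffer(
        "".join(same_len["seq"]).encode(), dtype=np.uint8
    ).reshape(len(same_len), len(q))
    idents = (mat == q).mean(axis=1)
    hits = [
        ReferenceHit(
            query_id="query",
            subject_id=r.subject_id,
            subject_taxon=r.taxon_id,
            bit_score=2.0 * float(ident) * len(q),
            percent_identity=100.0 * float(ident),
            coverage=100.0,
        )
        for r, ident in zip(same_len.itertuples(), idents)
    ]
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return hits[:top_n]
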