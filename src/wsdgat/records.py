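"""Shared record types for scaffolds and genes.

A scaffold is an assembled contig with an average read depth; its genes carry
1-based inclusive coordinates and the Pfam-style domain ids annotated on the
encoded protein. Unassembled proteins have no scaffold and are tracked only
through protein tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    domain_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.gene_id!r}: invalid interval")


@dataclass
class ScaffoldRecord:
    scaffold_id: str
    sample_id: str
    length: int
    read_depth: float
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        if self.read_depth <= 0:
            raise ValueError(f"scaffold {self.scaffold_id!r}: read_depth must be > 0")
        seen = set()
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.gene_id!r} extends past scaffold {self.scaffold_id!r}"
                )
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} on scaffold")
            seen.add(g.gene_id)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def write_depth_tsv(scaffolds: list[ScaffoldRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold_id\tsample_id\tread_depth\n")
        for s in scaffolds:
            fh.write(f"{s.scaffold_id}\t{s.sample_id}\t{s.read_depth:.6g}\n")


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"scaffold_id", "read_depth"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_gff3(scaffolds: list[ScaffoldRecord], path: str | Path) -> None:
    """Write gene models as GFF3 (CDS features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for s in scaffolds:
            fh.write(f"##sequence-region {s.scaffold_id} 1 {s.length}\n")
            for g in s.genes:
                attrs = f"ID={g.gene_id}"
                if g.domain_ids:
                    attrs += ";domains=" + ",".join(g.domain_ids)
                fh.write(
                    f"{s.scaffold_id}\twsdgat\tCDS\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t0\t{attrs}\n"
                )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read the 9-column GFF3 emitted by this package into a gene table
    (scaffold_id, gene_id, start, end, strand, domains)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            seqid, _src, _type, start, end, _score, strand, _phase, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            rows.append(
                {
                    "scaffold_id": seqid,
                    "gene_id": attr.get("ID", ""),
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                    "domains": attr.get("domains", ""),
                }
            )
    return pd.DataFrame(rows)
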