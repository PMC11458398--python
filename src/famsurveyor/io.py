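"""Gene models and on-disk formats.

The package works from three plain-text inputs: a protein FASTA, a CDS FASTA
and a GFF3 annotation.  Sequences travel through Biopython; the GFF3 subset
used here (gene / mRNA / exon / CDS features with ID= / Parent= attributes)
is read and written directly so that write -> read -> write is byte-stable.

Coordinates are 1-based inclusive on disk (GFF3 convention) and kept that way
on :class:`GeneModel`; per-chromosome gene ranks are 0-based order indices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Isoform",
    "GeneModel",
    "GeneSet",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_matrix",
    "write_matrix",
    "read_edge_list",
    "write_edge_list",
]


@dataclass
class Isoform:
    isoform_id: str
    protein: str
    cds: str
    exon_count: int = 1


@dataclass
class GeneModel:
    """One gene locus with its isoforms.

    ``start``/``end`` are 1-based inclusive base-pair coordinates; ``rank`` is
    the 0-based position of the gene in start order along its chromosome.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1
    isoforms: list[Isoform] = field(default_factory=list)

    def longest_isoform(self) -> Isoform:
        # ties broken by lexicographically smallest isoform id
        return min(self.isoforms, key=lambda iso: (-len(iso.protein), iso.isoform_id))


_SCAFFOLD_RE = re.compile(r"(scaffold|contig|^sc\d)", re.IGNORECASE)


def chromosome_sort_key(name: str, order: Sequence[str] | None = None):
    """Sort key placing named chromosomes (in ``order`` or natural numeric
    order) before scaffolds/contigs, which sort after them by name."""
    if order is not None and name in order:
        return (0, list(order).index(name), name)
    is_scaffold = 1 if _SCAFFOLD_RE.search(name) else 0
    m = re.search(r"(\d+)$", name)
    num = int(m.group(1)) if m else 10**9
    return (1 + is_scaffold, num, name)


class GeneSet:
    """An ordered collection of :class:`GeneModel` with rank bookkeeping."""

    def __init__(self, genes: Iterable[GeneModel], chromosome_order: Sequence[str] | None = None):
        self.genes: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        chroms = sorted(
            {g.chromosome for g in self.genes.values()},
            key=lambda c: chromosome_sort_key(c, chromosome_order),
        )
        self.chromosomes: list[str] = chroms
        self._assign_ranks()

    def _assign_ranks(self) -> None:
        for chrom in self.chromosomes:
            members = sorted(
                (g for g in self.genes.values() if g.chromosome == chrom),
                key=lambda g: (g.start, g.gene_id),
            )
            for i, g in enumerate(members):
                g.rank = i

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        for chrom in self.chromosomes:
            yield from sorted(
                (g for g in self.genes.values() if g.chromosome == chrom),
                key=lambda g: g.rank,
            )

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(path: str | Path, genes: GeneSet) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join(
                [g.chromosome, "famsurveyor", "gene", str(g.start), str(g.end), ".", g.strand, ".", attrs]
            )
        )
        for iso in g.isoforms:
            lines.append(
                "\t".join(
                    [g.chromosome, "famsurveyor", "mRNA", str(g.start), str(g.end), ".", g.strand, ".",
                     f"ID={iso.isoform_id};Parent={g.gene_id}"]
                )
            )
            # single-exon layout: exon and CDS span the locus
            for ftype in ("exon", "CDS"):
                lines.append(
                    "\t".join(
                        [g.chromosome, "famsurveyor", ftype, str(g.start), str(g.end), ".", g.strand,
                         "0" if ftype == "CDS" else ".",
                         f"ID={iso.isoform_id}.{ftype.lower()};Parent={iso.isoform_id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(
    path: str | Path,
    proteins: Mapping[str, str] | None = None,
    cds: Mapping[str, str] | None = None,
    chromosome_order: Sequence[str] | None = None,
) -> GeneSet:
    """Parse the gene/mRNA/exon/CDS subset of GFF3 into a :class:`GeneSet`.

    ``proteins`` and ``cds`` are FASTA dicts keyed by mRNA id; when given,
    sequences are attached to the corresponding isoforms.
    """
    genes: dict[str, GeneModel] = {}
    mrna_parent: dict[str, str] = {}
    exon_counts: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            continue
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f
        a = _parse_attrs(attrs)
        if ftype == "gene":
            gid = a["ID"]
            genes[gid] = GeneModel(gid, chrom, int(start), int(end), strand)
        elif ftype == "mRNA":
            mrna_parent[a["ID"]] = a["Parent"]
        elif ftype == "exon":
            parent = a.get("Parent", "")
            exon_counts[parent] = exon_counts.get(parent, 0) + 1
    for mrna_id, gid in mrna_parent.items():
        if gid not in genes:
            continue
        prot = (proteins or {}).get(mrna_id, "")
        c = (cds or {}).get(mrna_id, "")
        genes[gid].isoforms.append(
            Isoform(mrna_id, prot, c, exon_counts.get(mrna_id, 1))
        )
    return GeneSet(genes.values(), chromosome_order=chromosome_order)


# ---------------------------------------------------------------------------
# TSV matrices and edge lists

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Feature x sample matrix: first column = feature id, header = samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(path: str | Path, matrix: pd.DataFrame, index_label: str = "feature") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return df


def write_edge_list(path: str | Path, edges: pd.DataFrame) -> None:
    edges.to_csv(path, sep="\t", index=False)
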