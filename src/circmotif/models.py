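"""Shared genome / gene-annotation model and FASTA/GTF round-trip IO.

Internal coordinates are 0-based half-open throughout the package; the GTF
interface is 1-based inclusive as required by the format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from pyfaidx import Faidx

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

GTF_SOURCE = "circmotif"


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into an ordered name -> uppercase-sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    """Write sequences as wrapped FASTA and build a .fai index alongside."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    Faidx(str(path)).close()


@dataclass
class GeneModel:
    """A single-transcript gene: ordered exons on one strand of one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    biotype: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon ({s}, {e}) in {self.gene_id}")

    @property
    def transcript_id(self) -> str:
        return f"{self.gene_id}.t1"

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """Mature transcript sequence (reverse-complemented on the minus strand)."""
        seq = "".join(genome[self.chrom][s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


class Annotation:
    """Gene set with exon-boundary indexes used by the junction filters."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}
        self._exon_starts: dict[tuple[str, str, int], set[str]] = {}
        self._exon_ends: dict[tuple[str, str, int], set[str]] = {}
        for g in self.genes:
            for s, e in g.exons:
                self._exon_starts.setdefault((g.chrom, g.strand, s), set()).add(g.gene_id)
                self._exon_ends.setdefault((g.chrom, g.strand, e), set()).add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def genes_at_exon_start(self, chrom: str, strand: str, pos: int) -> set[str]:
        return self._exon_starts.get((chrom, strand, pos), set())

    def genes_at_exon_end(self, chrom: str, strand: str, pos: int) -> set[str]:
        return self._exon_ends.get((chrom, strand, pos), set())

    def genes_overlapping(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> list[GeneModel]:
        out = []
        for g in self.genes:
            if g.chrom != chrom:
                continue
            if strand is not None and g.strand != strand:
                continue
            if g.start < end and start < g.end:
                out.append(g)
        return out

    # -- GTF round trip ----------------------------------------------------

    def to_gtf(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                attrs = (
                    f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [g.chrom, GTF_SOURCE, "gene", str(g.start + 1), str(g.end), ".", g.strand, ".", attrs]
                    )
                    + "\n"
                )
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}"; '
                    f'gene_biotype "{g.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [g.chrom, GTF_SOURCE, "transcript", str(g.start + 1), str(g.end), ".", g.strand, ".", tattrs]
                    )
                    + "\n"
                )
                exons = g.exons if g.strand == "+" else list(reversed(g.exons))
                for i, (s, e) in enumerate(exons, start=1):
                    eattrs = tattrs + f' exon_number "{i}";'
                    fh.write(
                        "\t".join(
                            [g.chrom, GTF_SOURCE, "exon", str(s + 1), str(e), ".", g.strand, ".", eattrs]
                        )
                        + "\n"
                    )

    @classmethod
    def from_gtf(cls, path: str | os.PathLike) -> "Annotation":
        meta: dict[str, tuple[str, str, str]] = {}
        exons: dict[str, list[tuple[int, int]]] = {}
        order: list[str] = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    continue
                chrom, _src, feature, start, end, _score, strand, _frame, attr = fields[:9]
                attrs = _parse_gtf_attrs(attr)
                gid = attrs.get("gene_id", "")
                if feature == "gene":
                    meta[gid] = (chrom, strand, attrs.get("gene_biotype", "protein_coding"))
                    order.append(gid)
                elif feature == "exon":
                    if gid not in meta:
                        meta[gid] = (chrom, strand, attrs.get("gene_biotype", "protein_coding"))
                        order.append(gid)
                    exons.setdefault(gid, []).append((int(start) - 1, int(end)))
        genes = []
        for gid in order:
            chrom, strand, biotype = meta[gid]
            genes.append(GeneModel(gid, chrom, strand, biotype, exons.get(gid, [])))
        return cls(genes)


def _parse_gtf_attrs(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out
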