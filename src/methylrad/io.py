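"""Standard-format I/O: FASTA, FASTQ, GFF3, site TSVs.

External coordinates are 1-based inclusive (GFF3, site TSVs) or 0-based
half-open (BED); the conversion to the package-internal 0-based half-open
convention happens here and nowhere else.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AnnotationSet,
    GeneModel,
    GenomeAssembly,
    Methylome,
    MethylomeSite,
    MethylSiteLocus,
    RECOGNITION_PATTERNS,
    ValidationError,
)


class FormatError(ValueError):
    """A malformed record in an external file."""


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: GenomeAssembly, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.scaffolds.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> GenomeAssembly:
    scaffolds = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not scaffolds:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeAssembly(scaffolds)


# ---------------------------------------------------------------- FASTQ

def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> int:
    """Write (id, sequence, phred+33 quality string) triples; returns count."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            if len(seq) != len(qual):
                raise FormatError(f"{rid}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    reads = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4:
        raise FormatError(f"{path}: truncated FASTQ (line count not divisible by 4)")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{path}: malformed record at line {i + 1}")
        if len(seq) != len(qual):
            raise FormatError(f"{path}: length mismatch at line {i + 1}")
        reads.append((header[1:].split()[0], seq.upper(), qual))
    return reads


# ---------------------------------------------------------------- GFF3

def write_gff3(annotation: AnnotationSet, path: str | os.PathLike) -> None:
    """Emit gene/mRNA/exon/five_prime_UTR/three_prime_UTR features,
    1-based inclusive per the GFF3 standard."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.scaffold_lengths.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in annotation.genes:
            base = f"{g.scaffold}\tmethylrad\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(
                f"{base}gene\t{g.start + 1}\t{g.end}{tail}\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{base}mRNA\t{g.start + 1}\t{g.end}{tail}\tID={mrna};Parent={g.gene_id}\n"
            )
            for kind, ivs in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for s, e in ivs:
                    fh.write(f"{base}{kind}\t{s + 1}\t{e}{tail}\tParent={mrna}\n")


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff3(
    path: str | os.PathLike, scaffold_lengths: dict[str, int] | None = None
) -> AnnotationSet:
    """Read back the gene-model subset this package writes."""
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    seqlens: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, name, _, end = line.split()
                seqlens[name] = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            scaf, _, kind, start1, end1, _, strand, _, attrs = fields
            start, end = int(start1) - 1, int(end1)  # 1-based inclusive -> half-open
            at = _gff_attributes(attrs)
            if kind == "gene":
                genes[at["ID"]] = {
                    "scaffold": scaf, "strand": strand, "start": start, "end": end,
                    "exons": [], "utr5": [], "utr3": [],
                }
            elif kind == "mRNA":
                mrna_to_gene[at["ID"]] = at["Parent"]
            elif kind in ("exon", "five_prime_UTR", "three_prime_UTR"):
                gid = mrna_to_gene.get(at["Parent"], at["Parent"])
                slot = {"exon": "exons", "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}[kind]
                genes[gid][slot].append((start, end))
    models = [
        GeneModel(
            gene_id=gid,
            scaffold=g["scaffold"],
            strand=g["strand"],
            start=g["start"],
            end=g["end"],
            exons=sorted(g["exons"]),
            utr5=sorted(g["utr5"]),
            utr3=sorted(g["utr3"]),
        )
        for gid, g in genes.items()
    ]
    lengths = scaffold_lengths or seqlens
    if not lengths:
        raise FormatError(f"{path}: no ##sequence-region directives and no lengths given")
    return AnnotationSet(models, lengths)


# ---------------------------------------------------------------- methylome truth TSV

_METHYLOME_HEADER = ["scaffold", "mc_position", "strand", "pattern", "context",
                     "element_start", "mu_ck", "mu_eg", "direction"]


def write_methylome_tsv(methylome: Methylome, path: str | os.PathLike) -> None:
    """Truth table; mC positions are written 1-based."""
    with open(path, "w") as fh:
        fh.write("\t".join(_METHYLOME_HEADER) + "\n")
        for s in methylome:
            loc = s.locus
            fh.write(
                f"{loc.scaffold}\t{loc.mc_position + 1}\t{loc.strand}\t{loc.pattern}\t"
                f"{loc.context}\t{loc.element_start + 1}\t{s.mu_ck!r}\t{s.mu_eg!r}\t"
                f"{s.direction}\n"
            )


def read_methylome_tsv(path: str | os.PathLike) -> Methylome:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _METHYLOME_HEADER:
            raise FormatError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, 2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_METHYLOME_HEADER):
                raise FormatError(f"{path}:{lineno}: bad column count")
            locus = MethylSiteLocus(
                scaffold=f[0],
                element_start=int(f[5]) - 1,
                pattern=f[3],
                strand=f[2],
                mc_position=int(f[1]) - 1,
                context=f[4],
            )
            sites.append(MethylomeSite(locus, float(f[6]), float(f[7]), f[8]))
    return Methylome(sites)


def write_bed(rows: Iterable[tuple[str, int, str]], path: str | os.PathLike) -> None:
    """BED of site positions: (scaffold, 0-based mC position, strand)."""
    with open(path, "w") as fh:
        for scaf, pos, strand in rows:
            fh.write(f"{scaf}\t{pos}\t{pos + 1}\tmC\t0\t{strand}\n")
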