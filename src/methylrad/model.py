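"""Shared domain types for the MethylRAD pipeline.

Coordinates are 0-based, half-open everywhere inside the package; external
formats (GFF3, site TSVs) use 1-based inclusive coordinates and conversion
happens at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: FspEI-recognizable methylation elements scanned on the forward strand.
#: CCGG is palindromic so one forward scan covers both strands; CCTGG is the
#: reverse complement of CCAGG, so scanning all three patterns forward covers
#: both strands of the CWG motif as well. Values: (strand of the modified C,
#: offset of the mC from the element start in forward coordinates, context).
RECOGNITION_PATTERNS: dict[str, tuple[str, int, str]] = {
    "CCGG": ("+", 1, "CG"),
    "CCAGG": ("+", 1, "CWG"),
    "CCTGG": ("-", 3, "CWG"),
}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """A parameter or object violated its declared invariant."""


@dataclass(frozen=True, order=True)
class MethylSiteLocus:
    """One genomic FspEI recognition element.

    The methylated cytosine (mC) is the second C of the CC dinucleotide read
    5'->3' on its own strand; ``mc_position`` is its forward-strand coordinate.
    """

    scaffold: str
    element_start: int
    pattern: str
    strand: str
    mc_position: int
    context: str

    def __post_init__(self) -> None:
        if self.pattern not in RECOGNITION_PATTERNS:
            raise ValidationError(f"unknown recognition pattern {self.pattern!r}")
        expected = "CG" if self.pattern == "CCGG" else "CWG"
        if self.context != expected:
            raise ValidationError(
                f"context {self.context!r} inconsistent with pattern {self.pattern!r}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        """SiteKey used for count-matrix rows: (scaffold, mC position, strand)."""
        return (self.scaffold, self.mc_position, self.strand)


class GenomeAssembly:
    """Ordered collection of named scaffolds over the {A,C,G,T,N} alphabet."""

    _ALPHABET = frozenset("ACGTN")

    def __init__(self, scaffolds: dict[str, str]):
        if not scaffolds:
            raise ValidationError("assembly must contain at least one scaffold")
        clean: dict[str, str] = {}
        for name, seq in scaffolds.items():
            seq = seq.upper()
            if not seq:
                raise ValidationError(f"scaffold {name!r} is empty")
            if not set(seq) <= self._ALPHABET:
                bad = sorted(set(seq) - self._ALPHABET)
                raise ValidationError(f"scaffold {name!r} has invalid characters {bad}")
            clean[name] = seq
        self.scaffolds = clean

    def __getitem__(self, name: str) -> str:
        return self.scaffolds[name]

    def __contains__(self, name: str) -> bool:
        return name in self.scaffolds

    def __iter__(self) -> Iterator[str]:
        return iter(self.scaffolds)

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeAssembly) and self.scaffolds == other.scaffolds

    def length(self, name: str) -> int:
        return len(self.scaffolds[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())


@dataclass
class GeneModel:
    """A gene with exon structure; ``start``/``end`` span the transcript in
    genome (forward) coordinates regardless of strand."""

    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(f"{self.gene_id}: start must precede end")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site as a forward coordinate (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    @property
    def first_exon(self) -> tuple[int, int]:
        """The biologically 5'-most exon."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]


@dataclass
class SpliceWidths:
    """Widths of splice-site intervals (snpEff-style convention)."""

    site: int = 2         # acceptor/donor: bases at each intron end
    region_exonic: int = 3
    region_intronic: int = 8


class AnnotationSet:
    """Gene models plus derived intervals (introns, 2-kb flanks, promoters,
    splice sites), clipped to scaffold bounds."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        scaffold_lengths: dict[str, int],
        flank: int = 2000,
        splice: SpliceWidths | None = None,
    ):
        self.genes = sorted(genes, key=lambda g: (g.scaffold, g.start))
        self.scaffold_lengths = dict(scaffold_lengths)
        self.flank = flank
        self.splice = splice or SpliceWidths()
        for g in self.genes:
            if g.scaffold not in self.scaffold_lengths:
                raise ValidationError(f"{g.gene_id}: unknown scaffold {g.scaffold}")
            if g.end > self.scaffold_lengths[g.scaffold]:
                raise ValidationError(f"{g.gene_id}: extends past scaffold end")

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AnnotationSet)
            and self.genes == other.genes
            and self.scaffold_lengths == other.scaffold_lengths
        )

    def _clip(self, scaffold: str, start: int, end: int) -> tuple[int, int]:
        length = self.scaffold_lengths[scaffold]
        return max(0, start), min(length, end)

    def upstream(self, gene: GeneModel) -> tuple[int, int]:
        """2-kb interval 5' of the TSS, strand-aware, clipped."""
        if gene.strand == "+":
            return self._clip(gene.scaffold, gene.start - self.flank, gene.start)
        return self._clip(gene.scaffold, gene.end, gene.end + self.flank)

    def downstream(self, gene: GeneModel) -> tuple[int, int]:
        if gene.strand == "+":
            return self._clip(gene.scaffold, gene.end, gene.end + self.flank)
        return self._clip(gene.scaffold, gene.start - self.flank, gene.start)

    def promoter(self, gene: GeneModel) -> tuple[int, int]:
        """Promoter = the 2-kb upstream interval."""
        return self.upstream(gene)

    def splice_intervals(
        self, gene: GeneModel
    ) -> dict[str, list[tuple[int, int]]]:
        """Acceptor/donor (2 bp at intron ends, strand-aware) and splice-region
        (3 bp exonic + 8 bp intronic flank at every junction) intervals."""
        w = self.splice
        donors: list[tuple[int, int]] = []
        acceptors: list[tuple[int, int]] = []
        regions: list[tuple[int, int]] = []
        for istart, iend in gene.introns:
            left = (istart, istart + w.site)
            right = (iend - w.site, iend)
            if gene.strand == "+":
                donors.append(left)
                acceptors.append(right)
            else:
                donors.append(right)
                acceptors.append(left)
            # junction flanks: 3 bp exonic + 8 bp intronic at each junction;
            # the 2-bp acceptor/donor overlap is resolved by precedence
            regions.append((istart - w.region_exonic, istart))
            regions.append((istart, istart + w.region_intronic))
            regions.append((iend, iend + w.region_exonic))
            regions.append((iend - w.region_intronic, iend))
        clip = lambda iv: self._clip(gene.scaffold, *iv)  # noqa: E731
        return {
            "splice_site_donor": [clip(iv) for iv in donors],
            "splice_site_acceptor": [clip(iv) for iv in acceptors],
            "splice_site_region": [clip(iv) for iv in regions],
        }


@dataclass
class MethylomeSite:
    """Simulator truth for one locus: expected tag depth per condition."""

    locus: MethylSiteLocus
    mu_ck: float
    mu_eg: float
    direction: str  # hypo | hyper | none

    @property
    def differential(self) -> bool:
        return self.direction != "none"


class Methylome:
    """Truth model: per-locus expected depth under CK and EG conditions."""

    def __init__(self, sites: Iterable[MethylomeSite]):
        self.sites = list(sites)
        self._by_locus = {s.locus: s for s in self.sites}
        for s in self.sites:
            if s.mu_ck < 0 or s.mu_eg < 0:
                raise ValidationError("expected depths must be non-negative")
            if s.direction == "none" and s.mu_ck != s.mu_eg:
                raise ValidationError("non-differential site with unequal means")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[MethylomeSite]:
        return iter(self.sites)

    def __getitem__(self, locus: MethylSiteLocus) -> MethylomeSite:
        return self._by_locus[locus]

    def __contains__(self, locus: MethylSiteLocus) -> bool:
        return locus in self._by_locus

    def mu(self, locus: MethylSiteLocus, condition: str) -> float:
        site = self._by_locus[locus]
        return site.mu_eg if condition == "EG" else site.mu_ck
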