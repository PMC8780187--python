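"""FspEI digestion geometry and sequencing-library simulation.

FspEI recognizes a methylated cytosine in C^mC / ^mCDS contexts (D = A|T,
S = C|G) and nicks both strands at fixed offsets (N12/N16) 3' of the modified
base, releasing a 32-bp fragment with 4-base 3' overhangs. Operationally the
recognizable elements are the motifs CCGG (CG context) and CCAGG/CCTGG (CWG
context, W = A|T); the mC is the second C of the CC dinucleotide on its
strand. Tag depth at a site reports its methylation level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    GenomeAssembly,
    Methylome,
    MethylSiteLocus,
    RECOGNITION_PATTERNS,
    ValidationError,
    revcomp,
)

TAG_LENGTH = 32
OVERHANG = 4
#: default register of the mC inside the 32-mer: 15 bases 5' of it, 16 bases
#: 3' of it (both inside the 13-17 bp retention window)
MC_OFFSET_5P = 15


class BoundaryError(ValueError):
    """A locus sits too close to a scaffold edge for a full 32-bp tag."""


@dataclass(frozen=True)
class Fragment:
    locus: MethylSiteLocus
    start: int
    end: int
    tag: str
    mc_dist_5p: int
    mc_dist_3p: int
    overhang: int = OVERHANG

    def __post_init__(self) -> None:
        if self.end - self.start != TAG_LENGTH or len(self.tag) != TAG_LENGTH:
            raise ValidationError("fragment must span exactly 32 bp")
        if not (13 <= self.mc_dist_5p <= 17 and 13 <= self.mc_dist_3p <= 17):
            raise ValidationError("mC end distances must lie in [13, 17]")


@dataclass
class LibrarySpec:
    sample_id: str
    condition: str  # EG | CK
    scale: float = 1.0
    error_rate: float = 0.0
    adapter: str = ""
    seed: int = 0

    def validate(self) -> None:
        if self.condition not in ("EG", "CK"):
            raise ValidationError("condition must be 'EG' or 'CK'")
        if self.scale <= 0:
            raise ValidationError("library scale factor must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValidationError("error rate must lie in [0, 1)")


@dataclass
class ReadSet:
    sample_id: str
    reads: list[tuple[str, str, str]]  # (id, sequence, phred+33 qualities)
    truth: dict[str, MethylSiteLocus] = field(default_factory=dict)


def enumerate_recognition_sites(genome: GenomeAssembly) -> list[MethylSiteLocus]:
    """All forward-strand occurrences of CCGG/CCAGG/CCTGG, each emitted once.

    Because CCGG is its own reverse complement and CCTGG is the reverse
    complement of CCAGG, a forward scan of the three patterns covers both
    strands; palindromic CCGG elements yield a single locus keyed by the
    forward-strand mC. Overlapping occurrences are all reported.
    """
    loci: list[MethylSiteLocus] = []
    for name in sorted(genome):
        seq = genome[name]
        for pattern, (strand, mc_offset, context) in RECOGNITION_PATTERNS.items():
            pos = seq.find(pattern)
            while pos != -1:
                loci.append(
                    MethylSiteLocus(
                        scaffold=name,
                        element_start=pos,
                        pattern=pattern,
                        strand=strand,
                        mc_position=pos + mc_offset,
                        context=context,
                    )
                )
                pos = seq.find(pattern, pos + 1)
    loci.sort(key=lambda x: (x.scaffold, x.element_start, x.pattern))
    return loci


def fragment_for_site(
    locus: MethylSiteLocus, genome: GenomeAssembly, mc_offset_5p: int = MC_OFFSET_5P
) -> Fragment:
    """The 32-bp tag released around a locus.

    The element is centered so the mC lies ``mc_offset_5p`` bases from the
    tag's 5' end (default 15, hence 16 bases 3' of it) on the mC's own strand;
    bottom-strand loci yield the reverse complement of the forward substring.
    """
    seq = genome[locus.scaffold]
    d3 = TAG_LENGTH - 1 - mc_offset_5p
    if locus.strand == "+":
        start = locus.mc_position - mc_offset_5p
        end = locus.mc_position + d3 + 1
        tag = seq[start:end]
    else:
        # 5' direction on the bottom strand is toward higher forward coordinates
        start = locus.mc_position - d3
        end = locus.mc_position + mc_offset_5p + 1
        tag = revcomp(seq[start:end])
    if start < 0 or end > len(seq):
        raise BoundaryError(
            f"{locus.scaffold}:{locus.mc_position} too close to a scaffold edge "
            f"for a {TAG_LENGTH}-bp tag"
        )
    return Fragment(locus, start, end, tag, mc_offset_5p, d3)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, dispersion alpha) draws; Poisson limit at alpha = 0."""
    mean = np.asarray(mean, dtype=float)
    counts = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if alpha == 0:
        counts[pos] = rng.poisson(mean[pos])
    else:
        n = 1.0 / alpha
        p = n / (n + mean[pos])
        counts[pos] = rng.negative_binomial(n, p)
    return counts


_ERR_SUB = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACG"}


def simulate_library(
    genome: GenomeAssembly,
    sites: list[MethylSiteLocus],
    methylome: Methylome,
    spec: LibrarySpec,
    dispersion: float | None = None,
) -> ReadSet:
    """Draw per-site tag counts NB(mu_condition x scale, alpha) and emit reads.

    Reads are the site's 32-bp tag in a random orientation, with per-base
    substitution errors at ``spec.error_rate`` and an optional 3' adapter.
    Sites whose tag would run off a scaffold edge are skipped. Deterministic
    per seed.
    """
    spec.validate()
    for locus in sites:
        if locus not in methylome:
            raise ValidationError(f"methylome does not cover {locus.scaffold}:{locus.mc_position}")
    alpha = dispersion if dispersion is not None else 0.0
    rng = np.random.default_rng(spec.seed)
    reads: list[tuple[str, str, str]] = []
    truth: dict[str, MethylSiteLocus] = {}
    mus = np.array([methylome.mu(loc, spec.condition) * spec.scale for loc in sites])
    counts = _nb_counts(rng, mus, alpha)
    serial = 0
    for locus, k in zip(sites, counts):
        if k == 0:
            continue
        try:
            frag = fragment_for_site(locus, genome)
        except BoundaryError:
            continue
        for _ in range(int(k)):
            seq = frag.tag if rng.random() < 0.5 else revcomp(frag.tag)
            if spec.error_rate > 0:
                seq = _inject_errors(seq, spec.error_rate, rng)
            if spec.adapter:
                seq = seq + spec.adapter
            qual = "F" * len(seq)  # Q37 throughout; decay profiles are out of scope
            rid = f"{spec.sample_id}:{serial:08d}"
            serial += 1
            reads.append((rid, seq, qual))
            truth[rid] = locus
    return ReadSet(spec.sample_id, reads, truth)


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        out[i] = _ERR_SUB[out[i]][rng.integers(3)]
    return "".join(out)
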