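"""Synthetic genome, gene models, and methylome generation.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-scaffold plant-like genome, non-overlapping gene models with
exon/intron/UTR structure, and a methylome over FspEI elements with two
conditions (stressed EG vs control CK), a minority of differential sites, a
hypo-methylation majority among them, and negative-binomial tag depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    AnnotationSet,
    GeneModel,
    GenomeAssembly,
    Methylome,
    MethylomeSite,
    MethylSiteLocus,
    ValidationError,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticGenomeSpec:
    n_scaffolds: int = 4
    scaffold_length: int = 300_000
    gc_content: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if self.n_scaffolds < 1:
            raise ValidationError("n_scaffolds must be a positive integer")
        if self.scaffold_length < 1000:
            raise ValidationError("scaffold_length must be at least 1000 bp")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValidationError("gc_content must lie in [0, 1]")


@dataclass
class MethylomeSpec:
    """Truth-model parameters. ``baseline_level`` is an expected tag depth
    (MethylRAD depth reports methylation degree directly), not a methylation
    fraction."""

    fraction_methylated: float = 0.37
    baseline_level: float = 30.0
    baseline_cv: float = 0.6  # site-to-site spread of expected depth
    fraction_differential: float = 0.10
    effect_fold: float = 4.0
    fraction_hypo: float = 0.65
    dispersion: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("fraction_methylated", "fraction_differential", "fraction_hypo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.effect_fold <= 1.0:
            raise ValidationError("effect_fold must exceed 1")
        if self.dispersion < 0.0:
            raise ValidationError("dispersion must be non-negative")
        if self.baseline_level < 0.0:
            raise ValidationError("baseline_level must be non-negative")
        if self.baseline_cv < 0.0:
            raise ValidationError("baseline_cv must be non-negative")


def generate_genome(spec: SyntheticGenomeSpec) -> GenomeAssembly:
    """IID nucleotide scaffolds at the requested GC content, deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    scaffolds = {}
    for i in range(spec.n_scaffolds):
        draw = rng.choice(_BASES, size=spec.scaffold_length, p=probs)
        scaffolds[f"scaffold_{i + 1}"] = draw.tobytes().decode("ascii")
    return GenomeAssembly(scaffolds)


def generate_gene_models(
    genome: GenomeAssembly,
    n_genes: int,
    seed: int = 0,
    flank: int = 2000,
    min_gene_len: int = 1200,
    max_gene_len: int = 5000,
    max_exons: int = 6,
) -> AnnotationSet:
    """Place ``n_genes`` non-overlapping genes (including their 2-kb flanks)
    across the assembly. Roughly half of multi-exon genes receive UTRs."""
    if n_genes < 0:
        raise ValidationError("n_genes must be non-negative")
    rng = np.random.default_rng(seed)
    lengths = {name: genome.length(name) for name in genome}
    scaffold_names = list(genome)
    genes: list[GeneModel] = []
    if n_genes:
        # round-robin capacity-aware placement: walk each scaffold left to
        # right leaving >= flank on both sides of every gene
        cursors = {name: flank for name in scaffold_names}
        attempts = 0
        while len(genes) < n_genes:
            placed_any = False
            for name in scaffold_names:
                if len(genes) >= n_genes:
                    break
                glen = int(rng.integers(min_gene_len, max_gene_len + 1))
                gap = int(rng.integers(200, 1500))
                start = cursors[name] + gap
                end = start + glen
                if end + flank > lengths[name]:
                    continue
                # next gene's upstream flank must clear this gene's downstream flank
                cursors[name] = end + 2 * flank
                genes.append(_make_gene(f"gene_{len(genes) + 1:05d}", name, start, end, rng, max_exons))
                placed_any = True
            attempts += 1
            if not placed_any:
                raise ValidationError(
                    f"cannot place {n_genes} genes with {flank} bp flanks on this assembly "
                    f"(placed {len(genes)})"
                )
    return AnnotationSet(genes, lengths, flank=flank)


def _make_gene(
    gene_id: str, scaffold: str, start: int, end: int, rng: np.random.Generator, max_exons: int
) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    glen = end - start
    n_exons = int(rng.integers(1, max_exons + 1))
    # need n_exons exons (>=100 bp) separated by n_exons-1 introns (>=80 bp)
    while n_exons > 1 and n_exons * 100 + (n_exons - 1) * 80 > glen:
        n_exons -= 1
    if n_exons == 1:
        exons = [(start, end)]
    else:
        # draw interior boundaries then enforce minimum widths by even split fallback
        n_parts = 2 * n_exons - 1
        weights = rng.dirichlet(np.ones(n_parts) * 2.0)
        mins = np.array([100 if i % 2 == 0 else 80 for i in range(n_parts)])
        spare = glen - mins.sum()
        widths = mins + np.floor(weights * spare).astype(int)
        widths[-1] += glen - widths.sum()
        edges = start + np.concatenate([[0], np.cumsum(widths)])
        exons = [(int(edges[i]), int(edges[i + 1])) for i in range(0, n_parts, 2)]
    utr5: list[tuple[int, int]] = []
    utr3: list[tuple[int, int]] = []
    if n_exons > 1 and rng.random() < 0.5:
        # UTRs occupy part of the terminal exons (strand-aware)
        five = exons[0] if strand == "+" else exons[-1]
        three = exons[-1] if strand == "+" else exons[0]
        u5 = int(rng.integers(20, max(21, (five[1] - five[0]) // 2)))
        u3 = int(rng.integers(20, max(21, (three[1] - three[0]) // 2)))
        if strand == "+":
            utr5 = [(five[0], five[0] + u5)]
            utr3 = [(three[1] - u3, three[1])]
        else:
            utr5 = [(five[1] - u5, five[1])]
            utr3 = [(three[0], three[0] + u3)]
    return GeneModel(gene_id, scaffold, strand, start, end, exons, utr5, utr3)


def generate_methylome(sites: list[MethylSiteLocus], spec: MethylomeSpec) -> Methylome:
    """Assign truth depths to every enumerated recognition element.

    A ``fraction_methylated`` subset carries expected depth ``baseline_level``;
    of those, ``fraction_differential`` get an EG:CK effect of ``effect_fold``
    (hypo: EG = CK/fold with probability ``fraction_hypo``, else hyper:
    EG = CK*fold). Everything else has EG = CK.
    """
    spec.validate()
    if not sites:
        raise ValidationError("site list must be nonempty")
    rng = np.random.default_rng(spec.seed)
    n = len(sites)
    methylated = rng.random(n) < spec.fraction_methylated
    differential = methylated & (rng.random(n) < spec.fraction_differential)
    hypo = rng.random(n) < spec.fraction_hypo
    # site-to-site variation in methylation degree: gamma with the requested
    # mean and CV, so replicate libraries share a strong between-site signal
    if spec.baseline_cv > 0:
        shape = 1.0 / spec.baseline_cv**2
        baselines = spec.baseline_level * rng.gamma(shape, 1.0 / shape, size=n)
    else:
        baselines = np.full(n, spec.baseline_level)
    out = []
    for i, locus in enumerate(sites):
        if not methylated[i]:
            out.append(MethylomeSite(locus, 0.0, 0.0, "none"))
            continue
        mu_ck = float(baselines[i])
        if differential[i]:
            if hypo[i]:
                out.append(MethylomeSite(locus, mu_ck, mu_ck / spec.effect_fold, "hypo"))
            else:
                out.append(MethylomeSite(locus, mu_ck, mu_ck * spec.effect_fold, "hyper"))
        else:
            out.append(MethylomeSite(locus, mu_ck, mu_ck, "none"))
    return Methylome(out)
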