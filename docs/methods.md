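# Methods

## Overview

`methylrad` models methylation-dependent restriction sequencing (MethylRAD)
with the FspEI enzyme. FspEI recognizes a 5-methyl/5-hydroxymethyl cytosine
in C^mC and ^mCDS contexts (D = A|T, S = C|G) and cleaves both strands at
fixed N12/N16 offsets 3' of the modified base, releasing a 32-bp fragment
with 4-base 3' overhangs. Because only methylated elements are cut,
sequencing depth at a site is a direct readout of its methylation level —
the whole analysis operates on tag counts, never on bisulfite-style
methylation fractions.

Operationally the recognizable elements are the motifs CCGG (CG context) and
CCAGG / CCTGG (CWG context, W = A|T); the mC is the second C of the CC
dinucleotide read 5'->3' on its own strand. This pattern set is closed under
reverse complement (CCGG is palindromic; CCTGG is the reverse complement of
CCAGG), so one forward scan of a genome — or of a read — covers both
strands. A palindromic CCGG element is emitted once, keyed by its
forward-strand mC; this is also the row key under which the two tag
orientations of an element merge at counting time.

## Digestion geometry

The enzyme's cut register relative to the mC fixes the fragment: the tag is
32 bp with the mC 15 bases from the 5' end and 16 bases from the 3' end on
its own strand (both inside the 13-17 bp retention window the read filter
enforces; the register is overridable via `mc_offset_5p`). Bottom-strand
loci yield the reverse complement of the forward-strand substring. Loci
closer than a full tag to a scaffold edge raise `BoundaryError` and are
skipped (and recorded) by the simulator and the tag index.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes, not a
realistic plant genome (no repeats, no isochores, no N50 structure):

- **Genome**: IID nucleotides, 4 scaffolds x 300 kb at GC 0.45 by default.
  These defaults put roughly 5,000 FspEI elements on ~1.2 Mb so that the
  default methylome yields on the order of 2,000 reliable sites — the scale
  the statistical checks are specified at.
- **Gene models**: non-overlapping genes whose 2-kb flanks also stay
  disjoint, 1.2-5 kb long, 1-6 exons (exons >= 100 bp, introns >= 80 bp);
  about half of multi-exon genes get terminal-exon UTRs. Disjointness makes
  single-category feature assignment and region aggregation well-defined.
- **Methylome truth**: a fraction of elements (default 0.37, a typical
  plant mCG fraction) carries expected depth 30 on average; 10% of those are differential with a 4-fold effect, 65% of effects
  hypomethylated under stress (EG < CK), the hypo-majority
  drought methylomes typically show. Non-differential sites have identical EG/CK
  means by construction, and direction labels are definitionally consistent
  with the mu ratios.
- **Libraries**: per-site counts are negative binomial with shared
  dispersion alpha = 0.1 (Poisson at alpha = 0); reads are the site tag in
  random orientation with optional per-base substitution errors and a 3'
  adapter. Sample scale factors default to EG1/EG2/CK1/CK2 =
  1.0/1.15/0.95/1.25 to emulate library-size imbalance. Constant Q37
  qualities; no PCR duplicates, no quality decay, no partial digestion.

Because the generator writes exact tags, an error-free run with volume
normalization disabled recovers the truth table *exactly* — which is what
the end-to-end test asserts. Passing tests therefore demonstrate pipeline
correctness under the model's own assumptions, not robustness to real-data
artifacts (mapping ambiguity from repeats, chimeras, adapter read-through
beyond the modeled form).

## Read filtering funnel

Five ordered stages: (i) cross-sample volume normalization (seeded
downsampling to the cross-sample minimum by default; integer target or off
are available — downsampling is deliberately first, so later stages see
comparable volumes); (ii) adapter trimming (first adapter occurrence at or
after position 20, or a >= 5-base adapter prefix running off the 3' end;
iterated to a fixpoint so trimming is idempotent; remainders < 20 bp are
dropped); (iii) presence of a recognition motif; (iv) cut-distance: some
motif occurrence must imply an mC within 13-17 bp (inclusive) of either
read end — any occurrence, not just the leftmost, since a tag can carry a
second incidental motif; (v) quality: strictly more than 80% of bases at or
above Q20 (the quality threshold is configurable; the 80% and 8% constants
are the assay's standard criteria) and strictly fewer than 8% N. Funnel counts are
monotone by construction and reported in a raw/norm/adapter/enzyme/range/
clean table.

Distances are measured to the mC base itself (bases between the mC and the
read end), not to the nick site; the 13-17 retention window brackets that
reading.

## Quantification

Mapping replaces a general aligner: MethylRAD tags are fixed 32-mers
anchored at enzyme sites, so a hash of every site tag and its reverse
complement reproduces "uniquely mapped" semantics deterministically. A read
(its first 32 bases) matching exactly one locus — exactly, or at Hamming
distance 1 when `max_mismatch=1` — increments that locus; reads matching
several loci count as multiple-mapped and are excluded; the rest are
unmapped. Rows sharing a (scaffold, mC position, strand) key are summed and
their pattern sets unioned. The reliability filter keeps sites with depth
>= 5 in *every* library (the stricter of the two readings of the
threshold rule; a per-sample mode exists). RPM = depth / clean-read total x 1e6, with
the clean (high-quality) count as the library size, not the mapped count.
Sample agreement is summarized by Pearson correlation of site RPM vectors;
zero-variance samples yield NaN, never 0.

## Annotation

Each site gets exactly one feature category by precedence (most specific
first): splice acceptor > splice donor > splice region > 5'UTR > 3'UTR >
first exon > exon > intron > upstream > downstream > gene > intergenic.
Splice sites are 2 bp at each intron end; the splice region is 3 bp exonic
plus 8 bp intronic per junction (snpEff-style widths, overridable). "gene"
catches positions inside a span not covered by any sub-feature. Upstream /
downstream / promoter intervals are 2 kb, strand-aware, clipped to scaffold
bounds; the promoter is identical to the upstream interval.

Chromosome profiles use 10-kb windows at a 5-kb stride: all full windows,
plus one flagged partial terminal window when uncovered bases remain (so a
20-kb scaffold yields exactly three windows). Per window: detected sites,
theoretical enzyme sites, and summed depth; a site in k overlapping windows
contributes to all k.

Metaprofiles: each gene body is split into 100 equal windows and each 2-kb
flank into 101 windows (one-sided: upstream of the TSS, downstream of the
TTS), oriented 5'->3'; per-window RPM is summed within a gene and averaged
across qualifying genes (length >= 100 bp). Boundary sites go to the left
window (half-open bins).

## Differential methylation

- **Size factors**: median-of-ratios over sites with all-positive counts
  (median taken on the ratio scale, exactly the stated formula); fallback to
  library-total ratios with a warning when no such site exists.
- **Dispersion**: per-site method of moments, alpha_raw = max(0,
  (s^2 - mu)/mu^2) with s^2 the mean within-group variance of normalized
  counts, blended 50:50 with a monotone-decreasing isotonic trend of
  alpha vs mean fitted across sites. With 2v2 replication raw estimates are
  very noisy; the trend blend trades a little bias for a large variance
  reduction. Single-replicate designs must supply alpha explicitly.
- **Test**: NB conditional exact test. Condition on the summed count
  k_S = k_A + k_B; each group sum is NB with mean q*sum(s_j) and variance
  mean + alpha q^2 sum(s_j^2) (Poisson when the variance collapses); the
  two-sided p-value adds the probabilities of all splits no more likely than
  the observed one. At alpha -> 0 with equal size factors this reduces to
  the exact binomial conditional test. Enumeration is vectorized over the
  k_S + 1 splits, so gene-level totals in the tens of thousands remain fast.
- **Screen**: FC = baseMean_EG / baseMean_CK on normalized counts; a unit is
  up/hypermethylated iff FC > 2 and p < 0.05, down/hypomethylated iff
  FC < 0.5 and p < 0.05 — strict inequalities, on raw p;
  BH-adjusted p is reported alongside for FDR-based screening. FC at zero
  denominators is +inf (0/0 is NaN, never called); an optional +0.5
  pseudocount mode stabilizes FC but is off by default.
- **Levels**: gene level sums raw site depths within gene spans; promoter
  level sums within the 2-kb upstream intervals; zero-site regions are
  excluded from testing and tallied. Size factors and dispersions are
  re-estimated on the aggregated matrix at each level.
- **DMS-to-gene association**: a differential site links to the gene whose
  span or 2-kb flank contains it; the nearest such gene wins, ties broken by
  distance to TSS then lexicographic gene id; sites beyond all flanks stay
  unassociated.

Under the default null (5,000 sites, depth 30, alpha 0.1, 2v2 with the
default scale imbalance) the test's empirical P(p < 0.05) sits near nominal
(the acceptance band is 0.03-0.07), and the full screen is more conservative
because of the fold-change gate. At the default effect size (4-fold, depth
30) sensitivity exceeds 0.80. The end-to-end call-direction check compares
the hypo fraction among calls with the planted fraction among differential
truth sites *in the tested (reliable) set*, since the depth filter removes
some weakened hypo sites before testing; false-positive calls dilute the
observed ratio toward 1/2, which the 3-sigma binomial band accommodates at
the default scale.

## Enrichment

Hypergeometric upper tail, inclusive: p = P(X >= k) for
X ~ Hypergeometric(N, K, n) — the inclusive convention is asserted against
exhaustive enumeration for all N <= 12, since an off-by-one here is a
classic silent bug. BH step-up q-values are reported over all tested terms;
the significance flag uses raw p < 0.05, matching the screening rule. The
default background universe is the caller's choice; the pipeline uses genes
carrying at least one reliable site. Term content is user-supplied TSV; no
GO DAG propagation or pathway topology.

## Reproducibility and numerics

One global seed drives everything; stages receive sub-seeds
`(seed * 1_000_003 + stage_index) mod 2^31`, so any stage can be re-run in
isolation. The run manifest records the config hash, per-output SHA-256
checksums, and record counts; identical config + seed reproduces identical
checksums. Internal coordinates are 0-based half-open everywhere; GFF3 and
site TSVs are 1-based inclusive, BED is 0-based half-open, with conversion
confined to the I/O layer. Every screening and geometry constant (depth 5, FC 2/0.5,
p 0.05, 13-17 bp, 10 kb/5 kb, 2 kb, 100/101 bins, 32 bp) appears once as a
default in the module that owns it.

## Problem sizes used by the test suite

Unit tests run on 50-100 kb genomes (hundreds of sites); statistical
property tests use 2,000-5,000 simulated sites; the end-to-end check runs
the default ~1.2 Mb / ~2,000-reliable-site configuration, about 10 s on one
core. These sizes were chosen so the distributional claims (type-I error,
sensitivity, ratio recovery) have enough resolution while the whole suite
stays interactive.

## Known limitations

- 5mC and 5hmC are not distinguished (nor does the assay distinguish them).
- Shared per-library dispersion in the simulator; per-site dispersion is an
  extension point.
- Paired-end structure is not modeled; tags are single 32-mers (optionally
  adapter-extended), because the analysis uses only tag identity and depth.
- The exact-tag index assumes reads begin at a cut site, as MethylRAD reads
  do after trimming; it is not a general-purpose aligner.
- Enrichment results are only as meaningful as the user-supplied term map;
  the synthetic fixtures plant known enrichments for testing only.
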