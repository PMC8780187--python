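"""Tag mapping and site quantification.

MethylRAD tags are fixed 32-mers anchored at enzyme recognition sites, so an
exact / 1-mismatch hash lookup against the enumerated site tags reproduces
"uniquely mapped" read semantics deterministically: a read matching exactly
one locus increments that locus, reads matching several loci are counted as
multiple-mapped and excluded, and everything else is unmapped.

The count matrix is a pandas DataFrame with a (scaffold, position, strand)
MultiIndex, ``context`` / ``patterns`` metadata columns, and one integer
depth column per sample; per-sample clean (high-quality) read totals are the
library sizes used for RPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digestion import BoundaryError, TAG_LENGTH, fragment_for_site
from .model import GenomeAssembly, MethylSiteLocus, ValidationError, revcomp
from .readqc import Read

SITE_INDEX_NAMES = ["scaffold", "position", "strand"]
META_COLS = ["context", "patterns"]


@dataclass
class SiteCountMatrix:
    """Per-site x per-sample tag depths plus library sizes."""

    table: pd.DataFrame  # MultiIndex rows, columns META_COLS + sample ids
    library_sizes: dict[str, int]

    @property
    def samples(self) -> list[str]:
        return [c for c in self.table.columns if c not in META_COLS]

    @property
    def depths(self) -> pd.DataFrame:
        return self.table[self.samples]

    def validate(self) -> None:
        d = self.depths
        if (d.values < 0).any():
            raise ValidationError("negative depth")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate SiteKeys in matrix")
        for s in self.samples:
            if self.library_sizes.get(s, 0) < int(d[s].sum()):
                raise ValidationError(f"library size of {s} below its mapped depth total")


@dataclass
class MappingStats:
    clean_reads: int = 0
    unique_mapped: int = 0
    multiple_mapped: int = 0
    unmapped: int = 0
    too_short: int = 0

    @property
    def unique_ratio(self) -> float:
        return self.unique_mapped / self.clean_reads if self.clean_reads else 0.0

    @property
    def multiple_ratio(self) -> float:
        return self.multiple_mapped / self.clean_reads if self.clean_reads else 0.0

    @property
    def total_mapped_ratio(self) -> float:
        return self.unique_ratio + self.multiple_ratio


@dataclass
class SiteIndex:
    """32-mer tag -> loci lookup (both orientations indexed)."""

    tags: dict[str, list[MethylSiteLocus]] = field(default_factory=dict)
    skipped_edge_sites: list[MethylSiteLocus] = field(default_factory=list)

    @property
    def ambiguous_tags(self) -> set[str]:
        return {t for t, loci in self.tags.items() if len(set(l.key for l in loci)) > 1}

    def lookup(self, kmer: str) -> set[MethylSiteLocus]:
        return set(self.tags.get(kmer, ()))


def build_site_index(sites: list[MethylSiteLocus], genome: GenomeAssembly) -> SiteIndex:
    index = SiteIndex()
    for locus in sites:
        try:
            frag = fragment_for_site(locus, genome)
        except BoundaryError:
            index.skipped_edge_sites.append(locus)
            continue
        for key in (frag.tag, revcomp(frag.tag)):
            index.tags.setdefault(key, [])
            if locus not in index.tags[key]:
                index.tags[key].append(locus)
    return index


def _one_mismatch_hits(kmer: str, index: SiteIndex) -> set[MethylSiteLocus]:
    hits: set[MethylSiteLocus] = set()
    for i, base in enumerate(kmer):
        for sub in "ACGT":
            if sub != base:
                variant = kmer[:i] + sub + kmer[i + 1 :]
                hits |= index.lookup(variant)
    return hits


def map_tags(
    samples: dict[str, list[Read]],
    index: SiteIndex,
    max_mismatch: int = 1,
    library_sizes: dict[str, int] | None = None,
) -> tuple[SiteCountMatrix, dict[str, MappingStats]]:
    """Assign clean reads to loci; library sizes default to clean-read counts."""
    if max_mismatch not in (0, 1):
        raise ValidationError("max_mismatch must be 0 or 1")
    names = sorted(samples)
    counts: dict[tuple, dict] = {}
    stats = {name: MappingStats(clean_reads=len(samples[name])) for name in names}
    for name in names:
        st = stats[name]
        for _, seq, _ in samples[name]:
            if len(seq) < TAG_LENGTH:
                st.too_short += 1
                continue
            kmer = seq[:TAG_LENGTH]
            hits = index.lookup(kmer)
            if not hits and max_mismatch == 1:
                hits = _one_mismatch_hits(kmer, index)
            keys = {h.key for h in hits}
            if len(keys) == 1:
                st.unique_mapped += 1
                locus = next(iter(hits))
                row = counts.setdefault(
                    locus.key, {"context": locus.context, "patterns": {locus.pattern},
                                **{n: 0 for n in names}},
                )
                row["patterns"] = row["patterns"] | {locus.pattern}
                row[name] += 1
            elif len(keys) > 1:
                st.multiple_mapped += 1
            else:
                st.unmapped += 1
    table = _rows_to_table(counts, names)
    sizes = library_sizes or {n: len(samples[n]) for n in names}
    matrix = SiteCountMatrix(table, sizes)
    matrix.validate()
    return matrix, stats


def _rows_to_table(counts: dict[tuple, dict], names: list[str]) -> pd.DataFrame:
    if not counts:
        idx = pd.MultiIndex.from_arrays([[], [], []], names=SITE_INDEX_NAMES)
        return pd.DataFrame(columns=META_COLS + names, index=idx)
    keys = sorted(counts)
    idx = pd.MultiIndex.from_tuples(keys, names=SITE_INDEX_NAMES)
    data = {
        "context": [counts[k]["context"] for k in keys],
        "patterns": [",".join(sorted(counts[k]["patterns"])) for k in keys],
    }
    for n in names:
        data[n] = [int(counts[k][n]) for k in keys]
    return pd.DataFrame(data, index=idx)


def matrix_from_rows(
    rows: list[tuple[tuple[str, int, str], str, str, dict[str, int]]],
    library_sizes: dict[str, int],
) -> SiteCountMatrix:
    """Build a SiteCountMatrix from (key, context, patterns, depths) rows;
    duplicate keys are allowed here and resolved by merge_duplicate_sites."""
    names = sorted(library_sizes)
    idx = pd.MultiIndex.from_tuples([r[0] for r in rows], names=SITE_INDEX_NAMES)
    data = {
        "context": [r[1] for r in rows],
        "patterns": [r[2] for r in rows],
    }
    for n in names:
        data[n] = [int(r[3].get(n, 0)) for r in rows]
    return SiteCountMatrix(pd.DataFrame(data, index=idx), dict(library_sizes))


def merge_duplicate_sites(matrix: SiteCountMatrix) -> SiteCountMatrix:
    """Sum rows sharing a SiteKey; union their pattern sets."""
    t = matrix.table
    if not t.index.has_duplicates:
        return SiteCountMatrix(t.copy(), dict(matrix.library_sizes))
    grouped = t.groupby(level=SITE_INDEX_NAMES, sort=True)
    depths = grouped[matrix.samples].sum()
    meta = grouped.agg(
        context=("context", "first"),
        patterns=("patterns", lambda s: ",".join(sorted(set(",".join(s).split(","))))),
    )
    merged = pd.concat([meta, depths], axis=1)
    out = SiteCountMatrix(merged, dict(matrix.library_sizes))
    out.validate()
    return out


def filter_reliable_sites(
    matrix: SiteCountMatrix, min_depth: int = 5, mode: str = "all"
) -> SiteCountMatrix:
    """Retain sites with depth >= min_depth; ``all`` requires the threshold in
    every library, ``any`` in at least one."""
    if min_depth < 1:
        raise ValidationError("min_depth must be at least 1")
    if mode not in ("all", "any"):
        raise ValidationError("mode must be 'all' or 'any'")
    d = matrix.depths
    keep = (d >= min_depth).all(axis=1) if mode == "all" else (d >= min_depth).any(axis=1)
    return SiteCountMatrix(matrix.table.loc[keep].copy(), dict(matrix.library_sizes))


def rpm_normalize(matrix: SiteCountMatrix) -> pd.DataFrame:
    """RPM = depth / library high-quality read total x 1e6."""
    out = {}
    for s in matrix.samples:
        size = matrix.library_sizes.get(s, 0)
        if size <= 0:
            raise ValidationError(f"library size of {s} must be positive")
        out[s] = matrix.table[s] / size * 1_000_000.0
    return pd.DataFrame(out, index=matrix.table.index)


def context_summary(
    matrix: SiteCountMatrix, total_enzyme_sites: dict[str, int]
) -> pd.DataFrame:
    """Per sample and context: detected site count, percentage of all
    enumerated enzyme sites of that context, and mean depth over detected."""
    rows = []
    for sample in matrix.samples:
        for context in ("CG", "CWG"):
            sub = matrix.table[matrix.table["context"] == context][sample]
            detected = int((sub > 0).sum())
            total = total_enzyme_sites.get(context, 0)
            pct = 100.0 * detected / total if total > 0 else float("nan")
            mean_depth = float(sub[sub > 0].mean()) if detected else 0.0
            rows.append(
                {
                    "Sample": sample,
                    "Context": context,
                    "Site_Num": detected,
                    "Percent": pct,
                    "Mean_Depth": mean_depth,
                }
            )
    return pd.DataFrame(rows)


def sample_correlation(rpm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r over site RPM vectors; zero-variance samples give
    NaN (undefined), never 0."""
    if rpm.shape[1] < 2 or rpm.shape[0] < 2:
        raise ValidationError("need >=2 samples and >=2 sites for correlation")
    return rpm.corr(method="pearson")


def mapping_stats_table(stats: dict[str, MappingStats]) -> pd.DataFrame:
    rows = []
    for name, st in sorted(stats.items()):
        rows.append(
            {
                "Sample": name,
                "Clean_Reads": st.clean_reads,
                "Uniquely_Mapped_Reads": st.unique_mapped,
                "Uniquely_Mapped_Ratio": f"{100 * st.unique_ratio:.2f}%",
                "Multiple_Mapped_Reads": st.multiple_mapped,
                "Multiple_Mapped_Ratio": f"{100 * st.multiple_ratio:.2f}%",
                "Total_Mapped_Ratio": f"{100 * st.total_mapped_ratio:.2f}%",
            }
        )
    return pd.DataFrame(rows)
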