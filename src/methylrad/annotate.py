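"""Genomic feature annotation of methylation sites.

Every site receives exactly one feature category via a most-specific-first
precedence rule (an annotator can otherwise emit several overlapping labels
per position). Also provides 10-kb/5-kb sliding-window chromosome profiles
(actual vs theoretical site counts plus summed depth) and TSS / gene-body /
TTS metaprofiles with 101/100/101 bins of averaged RPM.
"""

from __future__ import annotations

from bisect import bisect_right

import numpy as np
import pandas as pd

from .model import AnnotationSet, GeneModel, GenomeAssembly, MethylSiteLocus, ValidationError
from .sitequant import SiteCountMatrix

#: highest to lowest precedence
FEATURE_PRECEDENCE = [
    "splice_site_acceptor",
    "splice_site_donor",
    "splice_site_region",
    "utr5prime",
    "utr3prime",
    "first_exon",
    "exon",
    "intron",
    "upstream",
    "downstream",
    "gene",
    "intergenic",
]


class _GeneLocator:
    """Locate the gene whose span +- flank contains a position; genes are
    placed non-overlapping including flanks, so at most one matches."""

    def __init__(self, annotation: AnnotationSet):
        self.flank = annotation.flank
        self.by_scaffold: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for g in annotation.genes:
            starts, genes = self.by_scaffold.setdefault(g.scaffold, ([], []))
            starts.append(g.start - self.flank)
            genes.append(g)

    def find(self, scaffold: str, pos: int) -> GeneModel | None:
        entry = self.by_scaffold.get(scaffold)
        if entry is None:
            return None
        starts, genes = entry
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        g = genes[i]
        if g.start - self.flank <= pos < g.end + self.flank:
            return g
        return None


def _contains(ivs: list[tuple[int, int]], pos: int) -> bool:
    return any(s <= pos < e for s, e in ivs)


def assign_feature(
    scaffold: str,
    position: int,
    annotation: AnnotationSet,
    locator: _GeneLocator | None = None,
    precedence: list[str] | None = None,
) -> str:
    """Highest-precedence feature category containing the position."""
    if scaffold not in annotation.scaffold_lengths:
        raise ValidationError(f"unknown scaffold {scaffold!r}")
    if not 0 <= position < annotation.scaffold_lengths[scaffold]:
        raise ValidationError(f"position {position} outside scaffold {scaffold!r}")
    locator = locator or _GeneLocator(annotation)
    order = precedence or FEATURE_PRECEDENCE
    g = locator.find(scaffold, position)
    if g is None:
        return "intergenic"
    splice = annotation.splice_intervals(g)
    first = [g.first_exon]
    members = {
        "splice_site_acceptor": splice["splice_site_acceptor"],
        "splice_site_donor": splice["splice_site_donor"],
        "splice_site_region": splice["splice_site_region"],
        "utr5prime": g.utr5,
        "utr3prime": g.utr3,
        "first_exon": first,
        "exon": g.exons,
        "intron": g.introns,
        "upstream": [annotation.upstream(g)],
        "downstream": [annotation.downstream(g)],
        "gene": [(g.start, g.end)],
    }
    for cat in order:
        if cat == "intergenic":
            continue
        if _contains(members.get(cat, []), position):
            return cat
    return "intergenic"


def feature_distribution(
    matrix: SiteCountMatrix, annotation: AnnotationSet
) -> pd.DataFrame:
    """Per sample and context: site count and fraction per feature category
    (a site counts for a sample when its depth there is nonzero)."""
    locator = _GeneLocator(annotation)
    cats = [
        assign_feature(scaf, pos, annotation, locator)
        for scaf, pos, _ in matrix.table.index
    ]
    cat_series = pd.Series(cats, index=matrix.table.index, name="category")
    rows = []
    for sample in matrix.samples:
        present = matrix.table[sample] > 0
        for context in ("CG", "CWG"):
            mask = present & (matrix.table["context"] == context)
            tally = cat_series[mask].value_counts()
            total = int(tally.sum())
            for cat in FEATURE_PRECEDENCE:
                n = int(tally.get(cat, 0))
                rows.append(
                    {
                        "Sample": sample,
                        "Context": context,
                        "Category": cat,
                        "Count": n,
                        "Fraction": n / total if total else 0.0,
                    }
                )
    return pd.DataFrame(rows)


def _windows(length: int, window: int, step: int) -> list[tuple[int, int, bool]]:
    """Window tiling: all full windows at the given stride, plus one flagged
    partial terminal window when uncovered bases remain."""
    if window < step or step <= 0:
        raise ValidationError("window must be >= step > 0")
    if length < window:
        return [(0, length, True)]
    out = [(s, s + window, False) for s in range(0, length - window + 1, step)]
    covered = out[-1][1]
    if covered < length:
        out.append((out[-1][0] + step, length, True))
    return out


def sliding_window_profile(
    matrix: SiteCountMatrix,
    all_sites: list[MethylSiteLocus],
    genome: GenomeAssembly,
    window: int = 10_000,
    step: int = 5_000,
) -> pd.DataFrame:
    """Per window: actual (detected) site count, theoretical enzyme-site
    count, and summed depth across samples. A site falling in k overlapping
    windows contributes to all k."""
    theo_pos: dict[str, np.ndarray] = {}
    for name in genome:
        theo_pos[name] = np.array(
            sorted(l.mc_position for l in all_sites if l.scaffold == name), dtype=int
        )
    det = matrix.table.reset_index()
    depth_total = matrix.depths.sum(axis=1).to_numpy()
    rows = []
    for name in sorted(genome):
        length = genome.length(name)
        sub = det[det["scaffold"] == name]
        positions = sub["position"].to_numpy()
        depths = depth_total[(det["scaffold"] == name).to_numpy()]
        tpos = theo_pos[name]
        for start, end, partial in _windows(length, window, step):
            in_win = (positions >= start) & (positions < end)
            rows.append(
                {
                    "scaffold": name,
                    "start": start,
                    "end": end,
                    "partial": partial,
                    "actual_sites": int(in_win.sum()),
                    "theoretical_sites": int(
                        np.searchsorted(tpos, end) - np.searchsorted(tpos, start)
                    ),
                    "depth": int(depths[in_win].sum()),
                }
            )
    return pd.DataFrame(rows)


def _bin_sum(
    positions: np.ndarray, values: np.ndarray, start: int, end: int, n_bins: int, reverse: bool
) -> np.ndarray:
    """Sum ``values`` into ``n_bins`` equal windows of [start, end); half-open
    bins, boundary sites go left. ``reverse`` orients 5'->3' for minus-strand."""
    out = np.zeros(n_bins)
    if end <= start:
        return out
    mask = (positions >= start) & (positions < end)
    if mask.any():
        rel = (positions[mask] - start) * n_bins // (end - start)
        rel = np.clip(rel, 0, n_bins - 1).astype(int)
        np.add.at(out, rel, values[mask])
    return out[::-1] if reverse else out


def metaprofile(
    rpm: pd.DataFrame,
    annotation: AnnotationSet,
    flank: int = 2000,
    body_bins: int = 100,
    flank_bins: int = 101,
) -> dict[str, dict[str, np.ndarray]]:
    """TSS-flank / gene-body / TTS-flank RPM profiles per sample.

    Each gene body is split into ``body_bins`` equal windows (5'->3'), each
    2-kb flank into ``flank_bins`` windows; per-window RPM is summed within a
    gene then averaged across genes. Output vectors have lengths
    ``flank_bins`` / ``body_bins`` / ``flank_bins``.
    """
    genes = [g for g in annotation.genes if g.end - g.start >= body_bins]
    if not genes:
        raise ValidationError("no gene long enough for the requested body binning")
    idx = rpm.index.to_frame(index=False)
    scafs = idx["scaffold"].to_numpy()
    positions = idx["position"].to_numpy()
    out: dict[str, dict[str, np.ndarray]] = {}
    for sample in rpm.columns:
        vals = rpm[sample].to_numpy(dtype=float)
        tss = np.zeros(flank_bins)
        body = np.zeros(body_bins)
        tts = np.zeros(flank_bins)
        for g in genes:
            m = scafs == g.scaffold
            pos, val = positions[m], vals[m]
            rev = g.strand == "-"
            if g.strand == "+":
                up = (g.start - flank, g.start)
                down = (g.end, g.end + flank)
            else:
                up = (g.end, g.end + flank)
                down = (g.start - flank, g.start)
            tss += _bin_sum(pos, val, up[0], up[1], flank_bins, rev)
            body += _bin_sum(pos, val, g.start, g.end, body_bins, rev)
            tts += _bin_sum(pos, val, down[0], down[1], flank_bins, rev)
        n = len(genes)
        out[sample] = {"tss": tss / n, "body": body / n, "tts": tts / n}
    return out


def metaprofile_table(profiles: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    rows = []
    for sample, segs in profiles.items():
        for segment, vec in segs.items():
            for i, v in enumerate(vec):
                rows.append({"Sample": sample, "Segment": segment, "Bin": i, "Mean_RPM": v})
    return pd.DataFrame(rows)
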