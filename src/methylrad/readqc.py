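"""Five-stage read filtering funnel.

Stages, applied in order: (i) cross-sample data-volume normalization,
(ii) adapter trimming, (iii) presence of an FspEI recognition pattern,
(iv) enzymatic cut-point distance within 13-17 bp of a read end,
(v) base-quality and N-content screen (>80% of bases at/above the phred
threshold, <8% N). The per-sample funnel counts mirror a raw/norm/adapter/
enzyme/range/clean statistics table and are monotone non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import RECOGNITION_PATTERNS, ValidationError, revcomp

Read = tuple[str, str, str]  # (id, sequence, phred+33 qualities)

_PATTERNS = list(RECOGNITION_PATTERNS)


@dataclass
class QCParams:
    min_cut_distance: int = 13
    max_cut_distance: int = 17
    min_quality_fraction: float = 0.80
    quality_threshold: int = 20
    max_n_fraction: float = 0.08
    adapter: str = ""
    downsample_target: int | str | None = "auto"  # auto | int | None (off)
    min_length_after_trim: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.min_cut_distance <= self.max_cut_distance:
            raise ValidationError("cut-distance window must satisfy 0 < min <= max")
        for name in ("min_quality_fraction", "max_n_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if isinstance(self.downsample_target, int) and self.downsample_target <= 0:
            raise ValidationError("downsample target must be positive")


@dataclass
class QCStats:
    """Per-sample funnel counts; each stage retains a subset of the previous."""

    raw_reads: int = 0
    norm_reads: int = 0
    adapter_reads: int = 0
    enzyme_reads: int = 0
    range_reads: int = 0
    clean_reads: int = 0

    @property
    def percent(self) -> float:
        return 100.0 * self.clean_reads / self.raw_reads if self.raw_reads else 0.0

    def check_monotone(self) -> None:
        seq = [self.raw_reads, self.norm_reads, self.adapter_reads,
               self.enzyme_reads, self.range_reads, self.clean_reads]
        if any(a < b for a, b in zip(seq, seq[1:])) or seq[-1] < 0:
            raise ValidationError(f"funnel counts not monotone: {seq}")


def normalize_volume(
    samples: dict[str, list[Read]], target: int | str | None = "auto", seed: int = 0
) -> dict[str, list[Read]]:
    """Seeded random downsampling; ``auto`` targets the cross-sample minimum."""
    if isinstance(target, int) and target <= 0:
        raise ValidationError("downsample target must be positive")
    if target is None or target == "off":
        return {k: list(v) for k, v in samples.items()}
    counts = {k: len(v) for k, v in samples.items()}
    goal = min(counts.values()) if target == "auto" else int(target)
    out = {}
    for i, (name, reads) in enumerate(sorted(samples.items())):
        n = min(goal, len(reads))
        if n == len(reads):
            out[name] = list(reads)
        else:
            rng = np.random.default_rng([seed, i])
            keep = np.sort(rng.choice(len(reads), size=n, replace=False))
            out[name] = [reads[j] for j in keep]
    return out


def trim_adapter(
    read: Read, adapter: str, min_length: int = 20, min_overlap: int = 5
) -> Read | None:
    """Truncate at the first adapter-prefix occurrence at/after ``min_length``
    (full occurrences anywhere past it, or a >= ``min_overlap`` adapter prefix
    running off the 3' end); drop reads left shorter than ``min_length``.
    Trimming iterates to a fixpoint, so it is idempotent."""
    if not adapter:
        return read
    rid, seq, qual = read
    while True:
        cut = None
        full = seq.find(adapter, min_length)
        if full != -1:
            cut = full
        else:
            # adapter running off the 3' end: longest adapter prefix that is a
            # read suffix, at least min_overlap long
            max_partial = min(len(adapter) - 1, len(seq) - min_length)
            for k in range(max_partial, min_overlap - 1, -1):
                if seq.endswith(adapter[:k]):
                    cut = len(seq) - k
                    break
        if cut is None:
            return (rid, seq, qual)
        if cut < min_length:
            return None
        seq, qual = seq[:cut], qual[:cut]


def has_enzyme_pattern(read_seq: str) -> tuple[bool, int | None]:
    """True iff the read or its reverse complement carries a recognition
    pattern; returns the leftmost match position on the read as given."""
    if not read_seq:
        raise ValidationError("empty read")
    best = None
    for pat in _PATTERNS:
        pos = read_seq.find(pat)
        if pos != -1 and (best is None or pos < best):
            best = pos
    if best is not None:
        return True, best
    rc = revcomp(read_seq)
    for pat in _PATTERNS:
        if pat in rc:
            # report the forward-read position of the leftmost forward-strand
            # projection of the reverse-complement match
            pos = rc.find(pat)
            fwd = len(read_seq) - pos - len(pat)
            return True, fwd
    return False, None


def _implied_mc_positions(seq: str) -> list[int]:
    """Read coordinates of the mC implied by every recognition-pattern
    occurrence, leftmost first. A forward scan suffices: the pattern set is
    closed under reverse complement, so a bottom-strand element always shows
    up as one of the three motifs on the read as given."""
    out: set[int] = set()
    for pat, (_, mc_off, _) in RECOGNITION_PATTERNS.items():
        pos = seq.find(pat)
        while pos != -1:
            out.add(pos + mc_off)
            pos = seq.find(pat, pos + 1)
    return sorted(out)


def cut_distance_ok(read: Read, params: QCParams) -> bool:
    """True iff some recognition-pattern occurrence implies an mC within
    [13, 17] bp of the 5' or 3' read end (distance = number of bases between
    the mC and that end), so a genuine enzymatic cut could have produced the
    fragment even when an incidental second motif sits elsewhere on it."""
    _, seq, _ = read
    mcs = _implied_mc_positions(seq)
    if not mcs:
        raise ValidationError("cut_distance_ok called on a pattern-free read")
    lo, hi = params.min_cut_distance, params.max_cut_distance
    for mc in mcs:
        d5 = mc
        d3 = len(seq) - 1 - mc
        if lo <= d5 <= hi or lo <= d3 <= hi:
            return True
    return False


def quality_ok(read: Read, params: QCParams) -> bool:
    """>80% of bases at/above the phred threshold AND <8% N (both strict)."""
    _, seq, qual = read
    if len(seq) != len(qual):
        raise ValidationError("sequence/quality length mismatch")
    if not seq:
        return False
    phred = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33
    frac_good = float(np.mean(phred >= params.quality_threshold))
    frac_n = seq.count("N") / len(seq)
    return frac_good > params.min_quality_fraction and frac_n < params.max_n_fraction


def run_qc(
    samples: dict[str, list[Read]], params: QCParams | None = None
) -> tuple[dict[str, list[Read]], dict[str, QCStats]]:
    """Apply stages (i)->(v) in order; returns clean reads and funnel stats."""
    params = params or QCParams()
    params.validate()
    stats = {name: QCStats(raw_reads=len(reads)) for name, reads in samples.items()}
    normed = normalize_volume(samples, params.downsample_target, params.seed)
    clean: dict[str, list[Read]] = {}
    for name, reads in normed.items():
        st = stats[name]
        st.norm_reads = len(reads)
        trimmed = [
            t for r in reads if (t := trim_adapter(r, params.adapter, params.min_length_after_trim))
        ]
        st.adapter_reads = len(trimmed)
        with_enzyme = [r for r in trimmed if has_enzyme_pattern(r[1])[0]]
        st.enzyme_reads = len(with_enzyme)
        in_range = [r for r in with_enzyme if cut_distance_ok(r, params)]
        st.range_reads = len(in_range)
        good = [r for r in in_range if quality_ok(r, params)]
        st.clean_reads = len(good)
        st.check_monotone()
        clean[name] = good
    return clean, stats


def stats_table(stats: dict[str, QCStats]) -> pd.DataFrame:
    """Funnel statistics in the conventional column layout."""
    rows = []
    for name, st in stats.items():
        rows.append(
            {
                "Sample": name,
                "Raw_Reads": st.raw_reads,
                "Norm_Reads": st.norm_reads,
                "Adapter_Reads": st.adapter_reads,
                "Enzyme_Reads": st.enzyme_reads,
                "Range_Reads": st.range_reads,
                "Clean_Reads": st.clean_reads,
                "Percent": f"{st.percent:.2f}%",
            }
        )
    return pd.DataFrame(rows)
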