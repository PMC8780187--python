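"""Differential methylation inference.

Tag depths are modeled as negative-binomial counts. Libraries are equalized
with median-of-ratios size factors, per-site dispersion is estimated by
method of moments with shrinkage toward a fitted mean-dispersion trend, and
the two-group comparison uses the NB conditional exact test: condition on the
summed count, enumerate every split between the group sums, and add up the
probabilities of splits no more likely than the observed one.

Screening is strict: a unit is called up/hypermethylated
when FC > 2 and p < 0.05, down/hypomethylated when FC < 0.5 and p < 0.05
(EG relative to CK); BH-adjusted p-values are reported alongside for users
who prefer an FDR screen.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .model import AnnotationSet, GeneModel, ValidationError
from .sitequant import META_COLS, SiteCountMatrix


@dataclass
class GroupDesign:
    """Sample -> condition map with exactly two nonempty conditions."""

    conditions: dict[str, str]
    test_group: str = "EG"
    ref_group: str = "CK"

    def __post_init__(self) -> None:
        groups = set(self.conditions.values())
        if groups != {self.test_group, self.ref_group}:
            raise ValidationError(
                f"design must contain exactly the groups "
                f"{{{self.test_group}, {self.ref_group}}}, got {sorted(groups)}"
            )

    def samples(self, group: str) -> list[str]:
        return sorted(s for s, g in self.conditions.items() if g == group)


@dataclass
class RegionSet:
    """Named intervals (gene spans or promoters) carrying gene ids."""

    regions: list[tuple[str, str, int, int]]  # (gene_id, scaffold, start, end)

    def __post_init__(self) -> None:
        for gid, _, s, e in self.regions:
            if s >= e:
                raise ValidationError(f"region {gid}: empty or inverted interval")

    @classmethod
    def gene_bodies(cls, annotation: AnnotationSet) -> "RegionSet":
        return cls([(g.gene_id, g.scaffold, g.start, g.end) for g in annotation.genes])

    @classmethod
    def promoters(cls, annotation: AnnotationSet) -> "RegionSet":
        out = []
        for g in annotation.genes:
            s, e = annotation.promoter(g)
            if e > s:
                out.append((g.gene_id, g.scaffold, s, e))
        return cls(out)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over sites with all-positive counts.

    factor_j = median_i ( count_ij / geometric_mean_i ), computed on the rows
    where every sample is nonzero; falls back to library-total ratios (with a
    warning) when no such row exists.
    """
    if counts.shape[1] < 2:
        raise ValidationError("need at least two samples for size factors")
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        warnings.warn("no site with all-positive counts; using library-size ratios")
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValidationError("a sample has zero total count")
        f = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(f, index=counts.columns)
    sub = mat[allpos]
    geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    factors = np.median(sub / geo, axis=0)
    return pd.Series(factors, index=counts.columns)


def estimate_dispersion(
    counts: pd.DataFrame,
    design: GroupDesign,
    factors: pd.Series | None = None,
    shrink: float = 0.5,
) -> pd.Series:
    """Per-site NB dispersion alpha by method of moments with trend shrinkage.

    Raw alpha = max(0, (s^2 - mu) / mu^2) where s^2 is the mean within-group
    variance of size-factor-normalized counts and mu their overall mean. The
    raw values are blended (default 50:50) with a monotone-decreasing
    isotonic trend fitted to alpha vs mean across sites.
    """
    groups = [design.samples(design.ref_group), design.samples(design.test_group)]
    if min(len(g) for g in groups) < 2:
        raise ValidationError(
            "dispersion estimation requires >=2 replicates per group; "
            "supply alpha explicitly for single-replicate designs"
        )
    if factors is None:
        factors = size_factors(counts)
    norm = counts / factors
    mu = norm.mean(axis=1).to_numpy()
    wvar = np.mean(
        [norm[g].var(axis=1, ddof=1).to_numpy() for g in groups], axis=0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, np.maximum(0.0, (wvar - mu) / mu**2), 0.0)
    ok = mu > 0
    if ok.sum() >= 10 and np.unique(mu[ok]).size > 1:
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        iso.fit(mu[ok], raw[ok])
        trend = np.where(ok, iso.predict(mu), 0.0)
    else:
        trend = np.full_like(raw, raw[ok].mean() if ok.any() else 0.0)
    alpha = (1.0 - shrink) * raw + shrink * trend
    return pd.Series(np.maximum(alpha, 0.0), index=counts.index)


def _group_pmf(total_sf: float, sum_sq_sf: float, q: float, alpha: float, support: np.ndarray):
    """pmf of a group's summed count: NB with mean q*total_sf and variance
    mean + alpha * q^2 * sum_sq_sf (Poisson when the variance collapses)."""
    mean = q * total_sf
    var = mean + alpha * q**2 * sum_sq_sf
    if mean <= 0:
        pmf = np.zeros(support.size)
        pmf[support == 0] = 1.0
        return pmf
    if var <= mean:
        return sps.poisson.pmf(support, mean)
    size = mean**2 / (var - mean)
    prob = size / (size + mean)
    return sps.nbinom.pmf(support, size, prob)


def nb_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    alpha: float,
) -> float:
    """NB conditional exact test for a two-group count comparison.

    Conditions on the summed raw count k_A + k_B, enumerates all splits
    (a, k_S - a), and returns the total conditional probability of splits no
    more likely than the observed one (two-sided by probability ordering).
    """
    ka, kb = int(np.sum(counts_a)), int(np.sum(counts_b))
    if ka < 0 or kb < 0:
        raise ValidationError("counts must be non-negative")
    if alpha < 0:
        raise ValidationError("dispersion must be non-negative")
    ks = ka + kb
    if ks == 0:
        return 1.0
    q = ks / (np.sum(sf_a) + np.sum(sf_b))
    support = np.arange(ks + 1)
    pa = _group_pmf(float(np.sum(sf_a)), float(np.sum(sf_a**2)), q, alpha, support)
    pb = _group_pmf(float(np.sum(sf_b)), float(np.sum(sf_b**2)), q, alpha, support)
    probs = pa * pb[::-1]  # P(A = a) * P(B = ks - a)
    total = probs.sum()
    if total <= 0:
        return 1.0
    obs = probs[ka]
    p = probs[probs <= obs * (1 + 1e-10)].sum() / total
    return float(min(1.0, max(p, np.finfo(float).tiny)))


@dataclass
class DiffOptions:
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    p_max: float = 0.05
    pseudocount: float = 0.0  # off by default; +0.5 stabilizes FC at zeros
    alpha_override: float | None = None


def call_differential(
    matrix: SiteCountMatrix,
    design: GroupDesign,
    options: DiffOptions | None = None,
) -> pd.DataFrame:
    """Per-unit baseMean / FC / p / direction / hyper-hypo table.

    Works on any unit level (site, gene, promoter) — the matrix rows define
    the units. Size factors and dispersions are computed from the matrix
    itself unless overridden.
    """
    opt = options or DiffOptions()
    counts = matrix.depths
    test_s = design.samples(design.test_group)
    ref_s = design.samples(design.ref_group)
    missing = (set(test_s) | set(ref_s)) - set(counts.columns)
    if missing:
        raise ValidationError(f"design samples missing from matrix: {sorted(missing)}")
    factors = size_factors(counts)
    if opt.alpha_override is not None:
        alphas = pd.Series(opt.alpha_override, index=counts.index)
    else:
        alphas = estimate_dispersion(counts, design, factors)
    norm = counts / factors
    base_mean = norm.mean(axis=1)
    base_a = norm[test_s].mean(axis=1) + opt.pseudocount
    base_b = norm[ref_s].mean(axis=1) + opt.pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = base_a / base_b
        log2fc = np.log2(fc)
    sf_a = factors[test_s].to_numpy()
    sf_b = factors[ref_s].to_numpy()
    ca = counts[test_s].to_numpy()
    cb = counts[ref_s].to_numpy()
    pvals = np.array(
        [
            nb_test(ca[i], cb[i], sf_a, sf_b, float(alphas.iloc[i]))
            for i in range(len(counts))
        ]
    )
    padj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    sig = pvals < opt.p_max
    fcv = fc.to_numpy()
    up = sig & (fcv > opt.fc_hi)
    down = sig & (fcv < opt.fc_lo)
    direction = np.where(up, "up", np.where(down, "down", "ns"))
    meth_class = np.where(up, "hyper", np.where(down, "hypo", "ns"))
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "baseMean_" + design.test_group: base_a,
            "baseMean_" + design.ref_group: base_b,
            "FC": fc,
            "log2FC": log2fc,
            "pval": pvals,
            "padj": padj,
            "dispersion": alphas,
            "direction": direction,
            "class": meth_class,
        },
        index=counts.index,
    )
    for col in META_COLS:
        if col in matrix.table.columns:
            out.insert(0, col, matrix.table[col])
    return out


def diff_summary(table: pd.DataFrame) -> dict[str, int]:
    d = table["direction"]
    return {
        "n_tested": int(len(table)),
        "n_up": int((d == "up").sum()),
        "n_down": int((d == "down").sum()),
        "n_hyper": int((table["class"] == "hyper").sum()),
        "n_hypo": int((table["class"] == "hypo").sum()),
    }


def aggregate_regions(matrix: SiteCountMatrix, regions: RegionSet) -> tuple[SiteCountMatrix, int]:
    """Region-level counts: sum of raw site depths whose mC lies in the
    region. Returns the matrix over regions with >=1 site and the count of
    zero-site regions (excluded from testing)."""
    by_scaffold: dict[str, list[tuple[int, int, str]]] = {}
    for gid, scaf, s, e in regions.regions:
        by_scaffold.setdefault(scaf, []).append((s, e, gid))
    for ivs in by_scaffold.values():
        ivs.sort()
    samples = matrix.samples
    sums: dict[str, np.ndarray] = {}
    depth = matrix.depths.to_numpy()
    for i, (scaf, pos, _) in enumerate(matrix.table.index):
        ivs = by_scaffold.get(scaf)
        if not ivs:
            continue
        j = bisect_right(ivs, (pos, np.inf, "")) - 1
        if j >= 0 and ivs[j][0] <= pos < ivs[j][1]:
            gid = ivs[j][2]
            sums.setdefault(gid, np.zeros(len(samples), dtype=int))
            sums[gid] += depth[i]
    all_ids = [gid for _, ivs in sorted(by_scaffold.items()) for *_, gid in ivs]
    n_empty = sum(1 for gid in all_ids if gid not in sums)
    idx = pd.Index(sorted(sums), name="region")
    table = pd.DataFrame(
        {s: [int(sums[g][k]) for g in idx] for k, s in enumerate(samples)}, index=idx
    )
    return SiteCountMatrix(table, dict(matrix.library_sizes)), n_empty


def associate_dms_to_genes(
    dms: pd.DataFrame, annotation: AnnotationSet
) -> pd.DataFrame:
    """Link each differential site to the gene whose span or 2-kb flank
    contains it; nearest such gene wins, ties broken by distance to TSS then
    gene id. Sites beyond every flank stay unassociated (gene id NA)."""
    flank = annotation.flank
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in annotation.genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    rows = []
    for key, row in dms.iterrows():
        scaf, pos = key[0], key[1]
        best: tuple[int, int, str] | None = None
        for g in by_scaffold.get(scaf, []):
            if g.start - flank <= pos < g.end + flank:
                dist = 0 if g.start <= pos < g.end else (
                    g.start - pos if pos < g.start else pos - g.end + 1
                )
                cand = (dist, abs(pos - g.tss), g.gene_id)
                if best is None or cand < best:
                    best = cand
        rows.append(
            {
                "scaffold": scaf,
                "position": pos,
                "direction": row["direction"],
                "class": row["class"],
                "gene_id": best[2] if best else pd.NA,
                "distance": best[0] if best else pd.NA,
            }
        )
    return pd.DataFrame(rows)
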