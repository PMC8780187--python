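"""Differential methylation: size factors, dispersion, NB exact test, calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methylrad import diffmeth as dm
from methylrad.model import AnnotationSet, GeneModel, ValidationError

from conftest import make_matrix

DESIGN = dm.GroupDesign({"EG1": "EG", "EG2": "EG", "CK1": "CK", "CK2": "CK"})


def nb_counts(rng, mean, alpha, size=None):
    if alpha == 0:
        return rng.poisson(mean, size)
    sz = 1.0 / alpha
    return rng.negative_binomial(sz, sz / (sz + mean), size)


def median_of_ratios_oracle(mat: np.ndarray) -> np.ndarray:
    """Textbook brute-force median-of-ratios, computed row by row."""
    keep = [i for i in range(mat.shape[0]) if all(mat[i] > 0)]
    geo = [np.prod(mat[i].astype(float)) ** (1.0 / mat.shape[1]) for i in keep]
    out = []
    for j in range(mat.shape[1]):
        ratios = sorted(mat[i, j] / geo[n] for n, i in enumerate(keep))
        out.append(np.median(ratios))
    return np.array(out)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2]})
        assert np.allclose(dm.size_factors(counts), 1.0)

    def test_doubled_column_has_double_factor(self):
        base = np.array([10, 40, 25, 7])
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        f = dm.size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            mat = rng.integers(1, 200, size=(50, 4))
            counts = pd.DataFrame(mat, columns=list("abcd"))
            assert np.allclose(dm.size_factors(counts), median_of_ratios_oracle(mat))

    def test_fallback_warns_without_all_positive_row(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.warns(UserWarning):
            f = dm.size_factors(counts)
        assert (f > 0).all()


class TestEstimateDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            nb_counts(rng, 30.0, 0.0, (2000, 4)), columns=["EG1", "EG2", "CK1", "CK2"]
        )
        a = dm.estimate_dispersion(counts, DESIGN, pd.Series(1.0, index=counts.columns))
        assert a.median() <= 0.05

    def test_constant_within_group_counts_give_zero_raw(self):
        counts = pd.DataFrame({"EG1": [10], "EG2": [10], "CK1": [40], "CK2": [40]})
        a = dm.estimate_dispersion(counts, DESIGN, pd.Series(1.0, index=counts.columns))
        assert a.iloc[0] == 0.0

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            nb_counts(rng, 50.0, 0.2, (2000, 4)), columns=["EG1", "EG2", "CK1", "CK2"]
        )
        a = dm.estimate_dispersion(counts, DESIGN, pd.Series(1.0, index=counts.columns))
        assert 0.1 <= a.median() <= 0.3

    def test_single_replicate_design_rejected(self):
        counts = pd.DataFrame({"EG1": [5], "CK1": [9]})
        design = dm.GroupDesign({"EG1": "EG", "CK1": "CK"})
        with pytest.raises(ValidationError):
            dm.estimate_dispersion(counts, design)


def conditional_enumeration_oracle(ka, kb, alpha):
    """Independent brute-force double loop over all splits of the total."""
    ks = ka + kb
    if ks == 0:
        return 1.0
    q = ks / 2.0
    if alpha == 0:
        pmf = lambda x: sps.poisson.pmf(x, q)  # noqa: E731
    else:
        var = q + alpha * q * q
        size = q * q / (var - q)
        pr = size / (size + q)
        pmf = lambda x: sps.nbinom.pmf(x, size, pr)  # noqa: E731
    probs = [pmf(a) * pmf(ks - a) for a in range(ks + 1)]
    total = sum(probs)
    obs = probs[ka]
    return sum(p for p in probs if p <= obs * (1 + 1e-10)) / total


class TestNBTest:
    ones = np.ones(1)

    def test_balanced_split_gives_p_one(self):
        p = dm.nb_test(np.array([20, 20]), np.array([20, 20]), np.ones(2), np.ones(2), 0.1)
        assert p == 1.0

    def test_zero_total_gives_p_one(self):
        assert dm.nb_test(np.zeros(2), np.zeros(2), np.ones(2), np.ones(2), 0.1) == 1.0

    @pytest.mark.parametrize("ka,kb", [(10, 30), (3, 7), (0, 5), (80, 120)])
    def test_poisson_limit_matches_binomial_conditional(self, ka, kb):
        # alpha -> 0 with equal size factors: the conditional law of the
        # observed split is Binomial(total, 1/2)
        got = dm.nb_test(np.array([ka]), np.array([kb]), self.ones, self.ones, 0.0)
        ks = ka + kb
        pmf = sps.binom.pmf(np.arange(ks + 1), ks, 0.5)
        expected = pmf[pmf <= pmf[ka] * (1 + 1e-10)].sum()
        assert got == pytest.approx(expected, abs=1e-6)

    def test_matches_enumeration_oracle_all_small_totals(self):
        for alpha in (0.0, 0.2):
            for ks in range(0, 51, 5):
                for ka in range(0, ks + 1, max(1, ks // 5)):
                    kb = ks - ka
                    got = dm.nb_test(
                        np.array([ka]), np.array([kb]), self.ones, self.ones, alpha
                    )
                    want = conditional_enumeration_oracle(ka, kb, alpha)
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            dm.nb_test(np.array([-1]), np.array([2]), self.ones, self.ones, 0.1)

    def test_type_one_error_near_nominal(self):
        # null NB simulation through the full estimation + testing path
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            {
                s: nb_counts(rng, 30.0 * sc, 0.1, 2000)
                for s, sc in [("EG1", 1.0), ("EG2", 1.15), ("CK1", 0.95), ("CK2", 1.25)]
            }
        )
        m = make_matrix({c: counts[c].tolist() for c in counts.columns})
        table = dm.call_differential(m, DESIGN)
        frac = (table["pval"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestCallDifferential:
    def test_fc_exactly_two_is_not_called(self):
        # strict inequality: FC == 2.0 stays ns even at tiny p; stable
        # background rows pin the size factors at 1
        bg = [30] * 50
        m = make_matrix(
            {"EG1": bg + [40], "EG2": bg + [40], "CK1": bg + [20], "CK2": bg + [20]}
        )
        table = dm.call_differential(m, DESIGN, dm.DiffOptions(alpha_override=0.0))
        assert table["FC"].iloc[-1] == pytest.approx(2.0)
        assert table["pval"].iloc[-1] < 0.05
        assert table["direction"].iloc[-1] == "ns"

    def test_strong_fold_called_up_and_hyper(self):
        bg = [30] * 20
        m = make_matrix(
            {"EG1": bg + [120], "EG2": bg + [120], "CK1": bg + [30], "CK2": bg + [30]}
        )
        table = dm.call_differential(m, DESIGN, dm.DiffOptions(alpha_override=0.05))
        assert table["direction"].iloc[-1] == "up"
        assert table["class"].iloc[-1] == "hyper"
        assert table["direction"].iloc[0] == "ns"

    def test_label_swap_maps_up_to_down(self):
        depths = {"EG1": [120, 8], "EG2": [110, 9], "CK1": [30, 33], "CK2": [28, 30]}
        m = make_matrix(depths)
        fwd = dm.call_differential(m, DESIGN, dm.DiffOptions(alpha_override=0.05))
        swapped_design = dm.GroupDesign(
            {"EG1": "CK", "EG2": "CK", "CK1": "EG", "CK2": "EG"}
        )
        rev = dm.call_differential(m, swapped_design, dm.DiffOptions(alpha_override=0.05))
        flip = {"up": "down", "down": "up", "ns": "ns"}
        assert rev["direction"].tolist() == [flip[d] for d in fwd["direction"]]

    def test_parameter_recovery_on_default_conditions(self):
        # 2000 reliable sites, 10% differential at 4-fold, depth 30, alpha 0.1,
        # 2v2: sensitivity >= 0.80 and call direction mix within 3 sigma of
        # the planted mix
        rng = np.random.default_rng(8)
        n = 2000
        diff = rng.random(n) < 0.10
        hypo = rng.random(n) < 0.65
        mu_eg = np.where(diff, np.where(hypo, 30 / 4, 30 * 4), 30.0)
        depths = {
            "EG1": nb_counts(rng, mu_eg * 1.0, 0.1),
            "EG2": nb_counts(rng, mu_eg * 1.15, 0.1),
            "CK1": nb_counts(rng, np.full(n, 30.0) * 0.95, 0.1),
            "CK2": nb_counts(rng, np.full(n, 30.0) * 1.25, 0.1),
        }
        m = make_matrix({k: v.tolist() for k, v in depths.items()})
        table = dm.call_differential(m, DESIGN)
        called = table["direction"].to_numpy() != "ns"
        sensitivity = called[diff].mean()
        assert sensitivity >= 0.80
        calls_hypo = (table["class"].to_numpy() == "hypo").sum()
        n_calls = called.sum()
        p_true = hypo[diff].mean()
        sigma = np.sqrt(p_true * (1 - p_true) / n_calls)
        assert abs(calls_hypo / n_calls - p_true) <= 3 * sigma


class TestRegions:
    def _annotation(self):
        genes = [
            GeneModel("gA", "chr1", "+", 0, 300, exons=[(0, 300)]),
            GeneModel("gB", "chr1", "+", 5000, 5400, exons=[(5000, 5400)]),
        ]
        return AnnotationSet(genes, {"chr1": 20_000})

    def test_gene_counts_sum_member_sites(self):
        m = make_matrix({"a": [3, 4, 9]}, positions=[100, 200, 5200])
        regions = dm.RegionSet.gene_bodies(self._annotation())
        agg, n_empty = dm.aggregate_regions(m, regions)
        assert agg.table.loc["gA", "a"] == 7
        assert agg.table.loc["gB", "a"] == 9
        assert n_empty == 0

    def test_empty_gene_reported_not_tested(self):
        m = make_matrix({"a": [3]}, positions=[100])
        agg, n_empty = dm.aggregate_regions(m, dm.RegionSet.gene_bodies(self._annotation()))
        assert list(agg.table.index) == ["gA"]
        assert n_empty == 1

    def test_gene_totals_bounded_by_column_total(self):
        m = make_matrix({"a": [3, 4, 9, 5]}, positions=[100, 200, 6000, 15_000])
        agg, _ = dm.aggregate_regions(m, dm.RegionSet.gene_bodies(self._annotation()))
        assert agg.table["a"].sum() <= m.depths["a"].sum()

    def test_promoters_are_2kb_upstream(self):
        regions = dm.RegionSet.promoters(self._annotation())
        assert (("gB", "chr1", 3000, 5000)) in regions.regions


class TestAssociateDMS:
    def _annotation(self):
        genes = [
            GeneModel("gA", "chr1", "+", 10_000, 12_000, exons=[(10_000, 12_000)]),
            GeneModel("gB", "chr1", "+", 22_000, 24_000, exons=[(22_000, 24_000)]),
        ]
        return AnnotationSet(genes, {"chr1": 60_000})

    def _dms(self, positions):
        idx = pd.MultiIndex.from_arrays(
            [["chr1"] * len(positions), positions, ["+"] * len(positions)],
            names=["scaffold", "position", "strand"],
        )
        return pd.DataFrame(
            {"direction": ["down"] * len(positions), "class": ["hypo"] * len(positions)},
            index=idx,
        )

    def test_site_inside_gene_body(self):
        out = dm.associate_dms_to_genes(self._dms([11_000]), self._annotation())
        assert out["gene_id"].iloc[0] == "gA"
        assert out["distance"].iloc[0] == 0

    def test_flank_rule_prefers_near_gene(self):
        # 1 kb upstream of gA, ~10 kb from gB
        out = dm.associate_dms_to_genes(self._dms([9_000]), self._annotation())
        assert out["gene_id"].iloc[0] == "gA"

    def test_site_beyond_all_flanks_unassociated(self):
        out = dm.associate_dms_to_genes(self._dms([50_000]), self._annotation())
        assert pd.isna(out["gene_id"].iloc[0])
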