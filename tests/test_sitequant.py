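"""Tag index, mapping, duplicate merging, reliability filter, RPM, summaries."""

import collections

import numpy as np
import pandas as pd
import pytest

from methylrad import sitequant as sq
from methylrad import synthio
from methylrad.digestion import LibrarySpec, fragment_for_site, simulate_library
from methylrad.model import GenomeAssembly, ValidationError, revcomp

from conftest import make_matrix


class TestSiteIndex:
    def test_single_site_indexes_both_orientations(self):
        g = GenomeAssembly({"s": "A" * 20 + "CCGG" + "G" * 20})
        from methylrad.digestion import enumerate_recognition_sites

        sites = enumerate_recognition_sites(g)
        index = sq.build_site_index(sites, g)
        assert len(index.tags) == 2  # tag + its (distinct) reverse complement
        (locus,) = sites
        for loci in index.tags.values():
            assert loci == [locus]

    def test_duplicated_context_flags_ambiguous(self):
        core = "A" * 14 + "CCGG" + "A" * 14
        g = GenomeAssembly({"s": core + "T" * 40 + core})
        from methylrad.digestion import enumerate_recognition_sites

        sites = enumerate_recognition_sites(g)
        index = sq.build_site_index(sites, g)
        assert index.ambiguous_tags

    def test_simulator_round_trip_lookup(self, small_genome, small_sites, small_methylome):
        index = sq.build_site_index(small_sites, small_genome)
        rs = simulate_library(
            small_genome, small_sites, small_methylome, LibrarySpec("CK1", "CK", seed=5),
            dispersion=0.1,
        )
        for rid, seq, _ in rs.reads[:500]:
            hits = index.lookup(seq)
            assert rs.truth[rid] in hits


class TestMapTags:
    def _index(self, genome, sites):
        return sq.build_site_index(sites, genome)

    def test_exact_read_counts_once(self, small_genome, small_sites):
        index = self._index(small_genome, small_sites)
        frag = fragment_for_site(small_sites[10], small_genome)
        matrix, stats = sq.map_tags({"a": [("r1", frag.tag, "F" * 32)]}, index)
        assert stats["a"].unique_mapped == 1
        assert matrix.depths["a"].sum() == 1

    def test_one_mismatch_assigned(self, small_genome, small_sites):
        index = self._index(small_genome, small_sites)
        frag = fragment_for_site(small_sites[10], small_genome)
        mutated = ("G" if frag.tag[0] != "G" else "T") + frag.tag[1:]
        matrix, stats = sq.map_tags({"a": [("r1", mutated, "F" * 32)]}, index, max_mismatch=1)
        assert stats["a"].unique_mapped == 1
        _, stats0 = sq.map_tags({"a": [("r1", mutated, "F" * 32)]}, index, max_mismatch=0)
        assert stats0["a"].unmapped == 1

    def test_multi_locus_read_excluded(self):
        core = "A" * 14 + "CCGG" + "A" * 14
        g = GenomeAssembly({"s": core + "T" * 40 + core})
        from methylrad.digestion import enumerate_recognition_sites

        sites = enumerate_recognition_sites(g)
        index = sq.build_site_index(sites, g)
        matrix, stats = sq.map_tags({"a": [("r1", core, "F" * 32)]}, index)
        assert stats["a"].multiple_mapped == 1
        assert matrix.depths.empty or matrix.depths["a"].sum() == 0

    def test_short_read_skipped_with_count(self, small_genome, small_sites):
        index = self._index(small_genome, small_sites)
        _, stats = sq.map_tags({"a": [("r1", "ACGT", "FFFF")]}, index)
        assert stats["a"].too_short == 1

    def test_end_to_end_depths_equal_truth(self, small_genome, small_sites, small_methylome):
        index = sq.build_site_index(small_sites, small_genome)
        samples, truth = {}, {}
        for sid, cond, seed in [("EG1", "EG", 1), ("CK1", "CK", 2)]:
            rs = simulate_library(
                small_genome, small_sites, small_methylome, LibrarySpec(sid, cond, seed=seed),
                dispersion=0.1,
            )
            samples[sid] = rs.reads
            truth[sid] = collections.Counter(l.key for l in rs.truth.values())
        matrix, _ = sq.map_tags(samples, index)
        merged = sq.merge_duplicate_sites(matrix)
        for key, row in merged.depths.iterrows():
            for sid in merged.samples:
                assert row[sid] == truth[sid].get(key, 0)
        for sid in merged.samples:
            assert merged.depths[sid].sum() == sum(truth[sid].values())


class TestMergeFilterRpm:
    def test_merge_sums_duplicate_keys(self):
        rows = [
            (("chr1", 10, "+"), "CG", "CCGG", {"a": 3}),
            (("chr1", 10, "+"), "CWG", "CCAGG", {"a": 4}),
        ]
        m = sq.matrix_from_rows(rows, {"a": 100})
        merged = sq.merge_duplicate_sites(m)
        assert len(merged.table) == 1
        assert merged.depths["a"].iloc[0] == 7
        assert merged.table["patterns"].iloc[0] == "CCAGG,CCGG"

    def test_merge_identity_on_distinct_keys(self):
        m = make_matrix({"a": [1, 2, 3]})
        merged = sq.merge_duplicate_sites(m)
        pd.testing.assert_frame_equal(merged.table, m.table)

    def test_merge_preserves_column_sums(self):
        rows = [
            (("chr1", 10, "+"), "CG", "CCGG", {"a": 3, "b": 1}),
            (("chr1", 10, "+"), "CG", "CCGG", {"a": 4, "b": 9}),
            (("chr1", 99, "-"), "CWG", "CCTGG", {"a": 5, "b": 2}),
        ]
        m = sq.matrix_from_rows(rows, {"a": 100, "b": 100})
        merged = sq.merge_duplicate_sites(m)
        assert merged.depths.sum().to_dict() == m.depths.sum().to_dict()

    def test_filter_requires_min_depth_in_every_library(self):
        m = make_matrix({"a": [5, 10, 9], "b": [5, 10, 4]})
        kept = sq.filter_reliable_sites(m, min_depth=5)
        assert len(kept.table) == 2  # (5,5) and (10,10) stay; (9,4) drops

    def test_filter_min_depth_one_is_identity_on_positive(self):
        m = make_matrix({"a": [1, 2], "b": [3, 4]})
        kept = sq.filter_reliable_sites(m, min_depth=1)
        pd.testing.assert_frame_equal(kept.table, m.table)

    def test_filter_rejects_bad_min_depth(self):
        m = make_matrix({"a": [1]})
        with pytest.raises(ValidationError):
            sq.filter_reliable_sites(m, min_depth=0)

    def test_rpm_formula(self):
        m = make_matrix({"a": [10, 0]}, library_sizes={"a": 1_000_000})
        rpm = sq.rpm_normalize(m)
        assert rpm["a"].tolist() == [10.0, 0.0]

    def test_rpm_full_library_is_one_million(self):
        m = make_matrix({"a": [5000]}, library_sizes={"a": 5000})
        assert sq.rpm_normalize(m)["a"].iloc[0] == 1_000_000.0

    def test_rpm_rejects_zero_library(self):
        m = make_matrix({"a": [1]}, library_sizes={"a": 0})
        m.library_sizes["a"] = 0
        with pytest.raises(ValidationError):
            sq.rpm_normalize(m)

    def test_rpm_sum_at_most_one_million(self, small_genome, small_sites, small_methylome):
        index = sq.build_site_index(small_sites, small_genome)
        rs = simulate_library(
            small_genome, small_sites, small_methylome, LibrarySpec("CK1", "CK", seed=3),
            dispersion=0.1,
        )
        matrix, _ = sq.map_tags({"CK1": rs.reads}, index)
        merged = sq.merge_duplicate_sites(matrix)
        assert sq.rpm_normalize(merged)["CK1"].sum() <= 1_000_000.0 + 1e-6

    def test_pipeline_commutes_with_sample_permutation(self):
        depths = {"a": [6, 2, 9], "b": [7, 8, 1], "c": [5, 5, 5]}
        m1 = sq.filter_reliable_sites(sq.merge_duplicate_sites(make_matrix(depths)), 5)
        m2 = sq.filter_reliable_sites(
            sq.merge_duplicate_sites(make_matrix(dict(reversed(depths.items())))), 5
        )
        assert set(m1.table.index) == set(m2.table.index)
        for s in depths:
            assert m1.depths[s].tolist() == m2.depths[s].tolist()


class TestSummaries:
    def test_context_summary_mean_depth(self):
        m = make_matrix({"a": [10, 20]}, contexts=["CG", "CG"])
        out = sq.context_summary(m, {"CG": 500, "CWG": 100})
        cg = out[(out["Sample"] == "a") & (out["Context"] == "CG")].iloc[0]
        assert cg["Site_Num"] == 2
        assert cg["Mean_Depth"] == 15.0
        assert cg["Percent"] == pytest.approx(100 * 2 / 500)

    def test_context_summary_matches_brute_force(self, small_genome, small_sites, small_methylome):
        index = sq.build_site_index(small_sites, small_genome)
        rs = simulate_library(
            small_genome, small_sites, small_methylome, LibrarySpec("EG1", "EG", seed=4),
            dispersion=0.1,
        )
        matrix, _ = sq.map_tags({"EG1": rs.reads}, index)
        merged = sq.merge_duplicate_sites(matrix)
        totals = {
            "CG": sum(1 for l in small_sites if l.context == "CG"),
            "CWG": sum(1 for l in small_sites if l.context == "CWG"),
        }
        out = sq.context_summary(merged, totals)
        for _, row in out.iterrows():
            sub = merged.table[merged.table["context"] == row["Context"]]["EG1"]
            detected = [d for d in sub if d > 0]
            assert row["Site_Num"] == len(detected)
            if detected:
                assert row["Mean_Depth"] == pytest.approx(sum(detected) / len(detected))

    def test_correlation_of_duplicated_column_is_one(self):
        rpm = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        corr = sq.sample_correlation(rpm)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_anticorrelated_columns_give_minus_one(self):
        x = pd.Series([1.0, 5.0, 2.0])
        rpm = pd.DataFrame({"a": x, "b": x.max() - x})
        assert sq.sample_correlation(rpm).loc["a", "b"] == pytest.approx(-1.0)

    def test_correlation_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        rpm = pd.DataFrame(rng.random((100, 3)), columns=["a", "b", "c"])
        corr = sq.sample_correlation(rpm)
        for i in "abc":
            for j in "abc":
                x, y = rpm[i].to_numpy(), rpm[j].to_numpy()
                manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                    np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
                )
                assert corr.loc[i, j] == pytest.approx(manual)

    def test_zero_variance_sample_gives_nan(self):
        rpm = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        assert np.isnan(sq.sample_correlation(rpm).loc["a", "b"])
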