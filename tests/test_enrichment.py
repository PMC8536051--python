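"""Signed log-space Fisher statistic, matrix assembly, clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import fisher_exact_two_sided
from vdfreq.catalog import SnpCatalog, SnpRecord
from vdfreq.enrichment import (
    build_matrix,
    classify_snps,
    cluster_populations,
    fisher_two_sided_log10,
    signed_enrichment,
)
from vdfreq.frequencies import GLOBAL, FrequencyTable


class TestFisher:
    def test_mode_table_gives_p_one(self):
        # equal proportions, observed table is the hypergeometric mode
        p, log10_p = fisher_two_sided_log10(10, 20, 25, 50)
        assert p == 1.0 and log10_p == 0.0

    def test_small_table_exact_value(self):
        # exhaustive enumeration over C(8,4)=70 outcomes gives 34/70
        p, log10_p = fisher_two_sided_log10(3, 4, 1, 4)
        assert p == pytest.approx(34 / 70, rel=1e-12)
        assert log10_p == pytest.approx(np.log10(34 / 70), rel=1e-9)

    def test_degenerate_margins(self):
        assert fisher_two_sided_log10(0, 10, 0, 20) == (1.0, 0.0)
        assert fisher_two_sided_log10(10, 10, 20, 20) == (1.0, 0.0)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            fisher_two_sided_log10(5, 4, 1, 4)
        with pytest.raises(ValueError):
            fisher_two_sided_log10(1, 0, 1, 4)

    def test_finite_for_extreme_counts(self):
        # 10^4 alleles, maximally separated: p underflows but log10 stays finite
        p, log10_p = fisher_two_sided_log10(10_000, 10_000, 0, 10_000)
        assert p == 0.0
        assert np.isfinite(log10_p) and log10_p < -1000

    def test_saturation_cap(self):
        _, capped = fisher_two_sided_log10(10_000, 10_000, 0, 10_000, cap=312.61)
        assert capped == pytest.approx(-312.61)

    @given(
        n1=st.integers(1, 40),
        n2=st.integers(1, 40),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exact_enumeration(self, n1, n2, data):
        k1 = data.draw(st.integers(0, n1))
        k2 = data.draw(st.integers(0, n2))
        p, _ = fisher_two_sided_log10(k1, n1, k2, n2)
        expected = float(fisher_exact_two_sided(k1, n1, k2, n2))
        assert p == pytest.approx(expected, rel=1e-11)

    @given(n1=st.integers(1, 30), n2=st.integers(1, 30), data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_scipy(self, n1, n2, data):
        k1 = data.draw(st.integers(0, n1))
        k2 = data.draw(st.integers(0, n2))
        p, _ = fisher_two_sided_log10(k1, n1, k2, n2)
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        assert p == pytest.approx(stats.fisher_exact(table).pvalue, rel=1e-7)

    def test_monotone_in_distance_from_expectation(self):
        # fixed margins: moving k_pop away from expectation never increases p
        n1, n2, K = 30, 50, 40
        expectation = K * n1 / (n1 + n2)
        lo, hi = max(0, K - n2), min(K, n1)
        ps = {k: fisher_two_sided_log10(k, n1, K - k, n2)[0] for k in range(lo, hi + 1)}
        for k in range(int(expectation), hi):
            assert ps[k + 1] <= ps[k] + 1e-12
        for k in range(lo + 1, int(expectation) + 1):
            assert ps[k - 1] <= ps[k] + 1e-12

    @given(
        n1=st.integers(1, 25), n2=st.integers(1, 25), data=st.data()
    )
    @settings(max_examples=100, deadline=None)
    def test_label_swap_symmetry(self, n1, n2, data):
        # swapping effect/other allele labels leaves |log10 p| unchanged
        k1 = data.draw(st.integers(0, n1))
        k2 = data.draw(st.integers(0, n2))
        _, lp = fisher_two_sided_log10(k1, n1, k2, n2)
        _, lp_swapped = fisher_two_sided_log10(n1 - k1, n1, n2 - k2, n2)
        assert lp == pytest.approx(lp_swapped, rel=1e-9, abs=1e-12)


def freq_rows(rows):
    return FrequencyTable.from_records(rows)


class TestSignedEnrichment:
    TABLE = freq_rows(
        [
            ("rs1", "POP", 0.75, 3, 4, "genotypes"),
            ("rs1", GLOBAL, 0.25, 1, 4, "genotypes"),
            ("rs2", "POP", 0.25, 1, 4, "genotypes"),
            ("rs2", GLOBAL, 0.75, 3, 4, "genotypes"),
            ("rs3", "POP", 0.5, 2, 4, "genotypes"),
            ("rs3", GLOBAL, 0.5, 2, 4, "genotypes"),
        ]
    )

    def test_enriched_positive(self):
        cell = signed_enrichment("rs1", "POP", self.TABLE)
        assert cell.signed_stat == pytest.approx(-np.log10(34 / 70), rel=1e-9)
        assert cell.signed_stat > 0

    def test_depleted_negative(self):
        assert signed_enrichment("rs2", "POP", self.TABLE).signed_stat < 0

    def test_tie_is_zero(self):
        assert signed_enrichment("rs3", "POP", self.TABLE).signed_stat == 0.0

    def test_sign_matches_frequency_difference(self):
        for rsid in ("rs1", "rs2", "rs3"):
            cell = signed_enrichment(rsid, "POP", self.TABLE)
            assert np.sign(cell.signed_stat) == np.sign(cell.eaf_pop - cell.eaf_bg)
            assert abs(cell.signed_stat) == pytest.approx(-cell.log10_p)


def tiny_catalog(rsids):
    pairs = [("A", "G"), ("C", "T")]
    return SnpCatalog(
        [
            SnpRecord(r, "1", 10 * i + 1, "G", "intron_variant", *pairs[i % 2], "catalog")
            for i, r in enumerate(rsids)
        ]
    )


class TestBuildMatrix:
    def test_shape_and_order(self, reference_catalog, reference_frequencies,
                             population_order):
        matrix = build_matrix(
            reference_catalog, reference_frequencies, population_order
        )
        assert matrix.shape == (29, 6)
        assert list(matrix.index) == reference_catalog.rsids
        assert list(matrix.columns) == population_order

    def test_identical_populations_give_zero_matrix(self):
        catalog = tiny_catalog(["rs1", "rs2"])
        rows = []
        for rsid in ("rs1", "rs2"):
            for pop in ("A", "B", GLOBAL):
                rows.append((rsid, pop, 0.5, 10, 20, "genotypes"))
        matrix = build_matrix(catalog, freq_rows(rows), ["A", "B"])
        assert (matrix.to_numpy() == 0).all()

    def test_missing_cell_propagates_nan(self):
        catalog = tiny_catalog(["rs1"])
        rows = [("rs1", GLOBAL, 0.5, 10, 20, "genotypes")]
        matrix = build_matrix(catalog, freq_rows(rows), ["A"])
        assert np.isnan(matrix.loc["rs1", "A"])

    def test_published_directional_example(
        self, reference_catalog, reference_frequencies, population_order
    ):
        # the RABGAP1 variant flips direction between Europeans and Koreans
        matrix = build_matrix(
            reference_catalog, reference_frequencies, population_order
        )
        assert matrix.loc["rs10818769", "EUR"] > 0
        assert matrix.loc["rs10818769", "KOR"] < 0

    def test_complement_background_subtracts_population(self):
        catalog = tiny_catalog(["rs1"])
        # global pools A (enriched) and B; complement background for A is B
        rows = [
            ("rs1", "A", 0.8, 16, 20, "genotypes"),
            ("rs1", "B", 0.2, 4, 20, "genotypes"),
            ("rs1", GLOBAL, 0.5, 20, 40, "genotypes"),
        ]
        inclusive = build_matrix(catalog, freq_rows(rows), ["A"])
        complement = build_matrix(
            catalog, freq_rows(rows), ["A"], complement_background=True
        )
        expected = fisher_two_sided_log10(16, 20, 4, 20)[1]
        assert complement.loc["rs1", "A"] == pytest.approx(-expected)
        assert complement.loc["rs1", "A"] > inclusive.loc["rs1", "A"]


class TestClassification:
    def test_all_zero_matrix_all_comparable(self):
        matrix = pd.DataFrame(np.zeros((5, 2)), columns=["A", "B"],
                              index=[f"rs{i}" for i in range(5)])
        c = classify_snps(matrix, "A")
        assert c.counts == (0, 0, 5)
        assert c.extreme == []

    def test_partition_sums_to_snp_count(self, reference_catalog,
                                         reference_frequencies, population_order):
        matrix = build_matrix(reference_catalog, reference_frequencies,
                              population_order)
        c = classify_snps(matrix, "KOR")
        assert sum(c.counts) == len(reference_catalog)

    def test_thresholds(self):
        matrix = pd.DataFrame(
            {"P": [150.0, -120.0, 0.5, -0.5]},
            index=["rs1", "rs2", "rs3", "rs4"],
        )
        c = classify_snps(matrix, "P", alpha=0.05, extreme_threshold=100)
        assert c.enriched == ["rs1"]
        assert c.depleted == ["rs2"]
        assert set(c.comparable) == {"rs3", "rs4"}
        assert set(c.extreme) == {"rs1", "rs2"}


class TestClustering:
    def test_identical_columns_merge_first_at_zero(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=20)
        matrix = pd.DataFrame(
            {"A": base, "B": base, "C": rng.normal(size=20)},
        )
        dendro = cluster_populations(matrix, metric="euclidean")
        assert dendro.linkage_matrix[0, 2] == 0.0  # first merge height
        left, right = dendro.root_bipartition()
        assert {frozenset({"A", "B"}), frozenset({"C"})} == {left, right}

    def test_single_column_raises(self):
        with pytest.raises(ValueError):
            cluster_populations(pd.DataFrame({"A": [1.0, 2.0]}))

    def test_newick_renders_all_leaves(self, printed_matrix):
        dendro = cluster_populations(printed_matrix)
        newick = dendro.to_newick()
        assert newick.endswith(";")
        for pop in printed_matrix.columns:
            assert pop in newick

    def test_published_bipartition_on_reference_matrix(self, printed_matrix):
        left, right = cluster_populations(printed_matrix).root_bipartition()
        assert {left, right} == {
            frozenset({"EUR", "AMR", "SAS"}),
            frozenset({"AFR", "EAS", "KOR"}),
        }
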