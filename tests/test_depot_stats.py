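import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import marbling as m

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


class TestDepotMeans:
    def test_mean_of_two_samples(self, dataset):
        mat = dataset.matrix
        imf = m.depot_means(mat, "IMF")
        probe = mat.probe_ids[0]
        expected = mat.values.loc[probe, mat.samples_for("IMF")].mean()
        assert imf[probe] == pytest.approx(expected)

    def test_unknown_tissue_lists_available(self, dataset):
        with pytest.raises(KeyError, match="IMF"):
            m.depot_means(dataset.matrix, "Liver")

    def test_means_match_brute_force(self, dataset):
        """Vectorized depot means equal per-probe python summation."""
        mat = dataset.matrix
        got = m.depot_means(mat, "SC")
        cols = mat.samples_for("SC")
        for probe in mat.probe_ids[:20]:
            manual = sum(mat.values.loc[probe, c] for c in cols) / len(cols)
            assert got[probe] == pytest.approx(manual, rel=1e-12)

    def test_pooling_uses_all_12_samples(self, dataset):
        assert len(dataset.matrix.samples_for("IMF")) == 12


class TestMATransform:
    def test_printed_worked_example(self):
        """The CH25H depot means give the printed MA-plot coordinates."""
        M, A = m.ma_transform(10.53, 9.01)
        assert round(M, 2) == 1.52
        assert round(A, 2) == 9.77

    def test_identity_case(self):
        assert m.ma_transform(7.3, 7.3) == (0.0, 7.3)

    @given(finite, finite)
    def test_algebraic_round_trip(self, a, b):
        M, A = m.ma_transform(a, b)
        assert A + M / 2 == pytest.approx(a, abs=1e-9)
        assert A - M / 2 == pytest.approx(b, abs=1e-9)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "m_val,expected", [(-1.14, -2.20), (-0.84, -1.79), (0.0, 1.00)]
    )
    def test_table_convention(self, m_val, expected):
        assert round(float(m.signed_fold_change(m_val)), 2) == expected

    @given(st.floats(min_value=1e-3, max_value=20))
    def test_antisymmetry(self, m_val):
        up = m.signed_fold_change(m_val)
        down = m.signed_fold_change(-m_val)
        assert down == pytest.approx(-up)
        assert abs(up) == pytest.approx(2**m_val)


class TestEqualVarianceTTest:
    def test_identical_groups(self):
        assert m.equal_variance_t_test([1.0, 2, 3], [1.0, 2, 3]) == 1.0

    def test_degenerate_variance_conventions(self):
        assert m.equal_variance_t_test([0.0, 0, 0, 0], [5.0, 5, 5, 5]) == 0.0
        assert m.equal_variance_t_test([5.0, 5, 5], [5.0, 5, 5]) == 1.0

    def test_matches_independent_implementation(self):
        """Random 12-vs-12 draws agree with scipy's pooled t-test to 1e-12."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = rng.normal(size=12)
            b = rng.normal(0.3, 1.2, size=12)
            ours = m.equal_variance_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True).pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_null_p_values_uniform(self):
        """Type-I calibration: null p-values pass a KS uniformity check."""
        rng = np.random.default_rng(5)
        a = rng.normal(size=(6000, 12))
        b = rng.normal(size=(6000, 12))
        p = m.equal_variance_t_test(a, b)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestPIF:
    def test_product_of_printed_values(self):
        """M = -1.14 at depot means 15.33/16.47 gives PIF = -18.126."""
        assert m.pif(-1.14, 15.33, 16.47) == pytest.approx(-18.126, abs=1e-9)

    def test_zero_difference(self):
        assert m.pif(0.0, 3.0, 3.0) == 0.0

    @given(st.floats(min_value=-5, max_value=5), st.floats(min_value=1, max_value=20))
    def test_linear_in_abundance(self, m_val, mean):
        one = m.pif(m_val, mean, mean)
        two = m.pif(m_val, 2 * mean, 2 * mean)
        assert two == pytest.approx(2 * one)


class TestPIFSignificance:
    def test_value_at_the_mean(self):
        z, p = m.pif_significance([1.0, 2.0, 3.0])
        assert z[1] == 0.0
        assert p[1] == 0.5

    def test_three_sigma_tail(self):
        v = np.concatenate([np.zeros(100), [1.0]])
        z, p = m.pif_significance(v)
        idx = np.argmax(np.abs(z))
        assert p[idx] == pytest.approx(stats.norm.sf(abs(z[idx])))
        assert stats.norm.sf(3.0) == pytest.approx(0.00135, abs=1e-5)

    def test_moments(self):
        rng = np.random.default_rng(2)
        z, _ = m.pif_significance(rng.normal(size=500))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_zero_spread_is_an_error(self):
        with pytest.raises(ValueError):
            m.pif_significance([2.0, 2.0, 2.0])


class TestCollapseProbes:
    def test_max_abs_pif_retained(self):
        table = pd.DataFrame(
            {"probe": ["p1", "p2"], "gene": ["G", "G"], "pif": [-18.1, 2.0]}
        )
        out = m.collapse_probes(table)
        assert list(out["pif"]) == [-18.1]

    def test_one_probe_per_gene_is_identity(self):
        table = pd.DataFrame(
            {"probe": ["p1", "p2"], "gene": ["G1", "G2"], "pif": [1.0, -2.0]}
        )
        out = m.collapse_probes(table)
        assert set(out["probe"]) == {"p1", "p2"}

    def test_tie_breaks_on_probe_id(self):
        table = pd.DataFrame(
            {"probe": ["pB", "pA"], "gene": ["G", "G"], "pif": [3.0, -3.0]}
        )
        assert list(m.collapse_probes(table)["probe"]) == ["pA"]

    def test_unmapped_probe_is_an_error(self):
        table = pd.DataFrame({"probe": ["p1"], "pif": [1.0]})
        pmap = pd.Series([], dtype=str, index=pd.Index([], name="probe"))
        with pytest.raises(KeyError):
            m.collapse_probes(table, pmap)

    def test_matches_exhaustive_scan(self, gene_table, dataset):
        """Each output row carries the maximal |PIF| within its gene group."""
        full = m.score_table(dataset.matrix, "IMF", "SC", dataset.probe_map)
        by_gene = full.groupby("gene")["pif"].apply(lambda s: s.abs().max())
        merged = gene_table.set_index("gene")["pif"].abs()
        assert len(gene_table) == full["gene"].nunique()
        pd.testing.assert_series_equal(
            merged.sort_index(), by_gene.sort_index(), check_names=False
        )


class TestSelectExtreme:
    @pytest.mark.parametrize("fraction,expected", [(0.01, 145), (0.05, 724)])
    def test_reference_table_sizes(self, fraction, expected):
        """1% of 14,476 ranked genes is 145 records and 5% is 724."""
        table = pd.DataFrame({"pif": np.linspace(-5, 5, 14476)})
        assert len(m.select_extreme(table, fraction, "down")) == expected

    def test_full_fraction_returns_all(self):
        table = pd.DataFrame({"pif": [1.0, 2.0, 3.0]})
        assert len(m.select_extreme(table, 1.0, "up")) == 3

    def test_direction_selects_sign(self):
        table = pd.DataFrame({"pif": [-9.0, 0.0, 9.0]})
        assert m.select_extreme(table, 0.34, "up")["pif"].iloc[0] == 9.0
        assert m.select_extreme(table, 0.34, "down")["pif"].iloc[0] == -9.0

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            m.select_extreme(pd.DataFrame({"pif": [1.0]}), 0.0, "up")


class TestTabulatePanel:
    def test_values_equal_direct_lookups(self, dataset, gene_table):
        means = m.depot_mean_table(dataset.matrix)
        panel = list(gene_table["gene"].iloc[:3])
        report, missing = m.tabulate_panel(panel, means, gene_table)
        assert missing == []
        for _, row in report.iterrows():
            assert row["IMF"] == pytest.approx(
                round(means.at[row["probe"], "IMF"], 2)
            )

    def test_empty_panel(self, dataset, gene_table):
        means = m.depot_mean_table(dataset.matrix)
        report, missing = m.tabulate_panel([], means, gene_table)
        assert report.empty and missing == []

    def test_unresolved_gene_reported_not_fatal(self, dataset, gene_table):
        means = m.depot_mean_table(dataset.matrix)
        report, missing = m.tabulate_panel(["NOT_A_GENE"], means, gene_table)
        assert missing == ["NOT_A_GENE"]
        assert report.empty
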