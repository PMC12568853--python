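"""Correlation PCA summaries and the nonparametric zone comparison."""

import numpy as np
import pandas as pd
import pytest

from roaddust import ConcentrationMatrix, ValidationError, compare_zones, contributions, pca, select_components
from roaddust.datamodel import IndexTable
from roaddust.classification import classify
from roaddust.pca import PcaResult


def _frame(arr, metals=None):
    arr = np.asarray(arr, dtype=float)
    metals = metals or [f"m{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"S{i}" for i in range(arr.shape[0])], columns=metals)


class TestPca:
    def test_two_perfectly_correlated_metals(self):
        x = np.linspace(1, 9, 12)
        res = pca(_frame(np.column_stack([x, 3 * x + 1])))
        np.testing.assert_allclose(res.eigenvalues, [2.0, 0.0], atol=1e-12)
        # symmetric case: each metal contributes half of PC1
        np.testing.assert_allclose(res.contributions_pct["PC1"], [50.0, 50.0], atol=1e-9)

    def test_explained_percent_sums_to_hundred(self):
        rng = np.random.default_rng(0)
        res = pca(_frame(rng.lognormal(0, 1, size=(25, 6))))
        assert res.explained_pct.sum() == pytest.approx(100.0)
        assert res.eigenvalues.sum() == pytest.approx(6.0)

    def test_independent_metals_eigenvalues_near_one(self):
        rng = np.random.default_rng(1)
        res = pca(_frame(rng.normal(size=(4000, 5))))
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=0.15)

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(2)
        df = _frame(rng.lognormal(0, 0.5, size=(15, 4)))
        res = pca(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        recon = res.site_scores.to_numpy() @ res.eigenvectors.to_numpy().T
        np.testing.assert_allclose(recon, Z.to_numpy(), atol=1e-8)

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        df = _frame(rng.lognormal(0, 0.5, size=(20, 4)))
        scaled = df * [10.0, 0.01, 3.0, 500.0] + [1.0, 0.0, 7.0, 2.0]
        a, b = pca(df), pca(scaled)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-8)

    def test_cos2_sums_to_one_per_metal(self):
        rng = np.random.default_rng(4)
        res = pca(_frame(rng.lognormal(0, 1, size=(12, 5))))
        np.testing.assert_allclose(res.cos2.sum(axis=1), 1.0, rtol=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        res = pca(_frame(rng.normal(size=(30, 6))))
        for c in res.loadings.columns:
            col = res.loadings[c]
            assert col.loc[col.abs().idxmax()] > 0

    def test_constant_column_names_metal(self):
        df = _frame(np.ones((5, 2)), metals=["Cd", "Ni"])
        df["Cd"] = [1, 2, 3, 4, 5.0]
        with pytest.raises(ValidationError, match="Ni"):
            pca(df)

    def test_zone_slicing(self, small_conc):
        res = pca(small_conc, zone="A")
        assert res.site_scores.shape[0] == 6


class TestComponentSelection:
    def _result(self, eigenvalues):
        w = np.asarray(eigenvalues, dtype=float)
        explained = 100 * w / w.sum() * (len(w) / len(w))  # correlation scale
        explained = 100 * w / len(w)
        dummy = pd.DataFrame(np.zeros((len(w), len(w))))
        return PcaResult(w, explained, np.cumsum(explained), dummy, dummy, dummy, dummy, dummy)

    def test_kaiser_count(self):
        sel = select_components(self._result([3.2, 2.1, 1.5, 0.9, 0.3]))
        assert sel.kaiser_count == 3
        assert sel.chosen == 3  # cumulative at 3 is 85% >= 80%

    def test_extend_past_kaiser_until_variance_reached(self):
        sel = select_components(self._result([5.0, 1.2, 0.9, 0.8, 0.7, 0.4, 0.5, 0.3, 0.1, 0.1]))
        # Kaiser count 2 explains 62% < 80% -> extend to the variance count
        assert sel.kaiser_count == 2
        assert sel.chosen == sel.variance_count > 2

    def test_all_eigenvalues_one_falls_back_to_variance_rule(self):
        sel = select_components(self._result([1.0, 1.0, 1.0, 1.0]))
        assert sel.kaiser_count == 0
        assert sel.chosen == sel.variance_count == 4

    def test_combined_contributions_weighting(self):
        rng = np.random.default_rng(6)
        res = pca(_frame(rng.lognormal(0, 1, size=(15, 4))))
        multi = contributions(res, [1, 2])
        assert multi.sum() == pytest.approx(100.0)
        lam = res.eigenvalues[:2]
        manual = (res.contributions_pct[["PC1", "PC2"]] * lam).sum(axis=1) / lam.sum()
        pd.testing.assert_series_equal(multi, manual.rename("contribution_pct"))


def _index_table(values):
    df = pd.DataFrame(values)
    return IndexTable("PI", df, classify("PI", df))


class TestCompareZones:
    def test_hand_computed_kruskal(self):
        tables = {"PI": {"A": _index_table({"m": [1.0, 2.0, 3.0]}),
                         "B": _index_table({"m": [10.0, 11.0, 12.0]})}}
        out = compare_zones(tables)
        assert out.loc["PI", "H"] == pytest.approx(27 / 7, abs=1e-3)  # 3.857
        assert out.loc["PI", "p"] == pytest.approx(0.0495, abs=1e-3)

    def test_identical_groups_h_zero(self):
        tables = {"PI": {"A": _index_table({"m": [2.0, 2.0, 2.0]}),
                         "B": _index_table({"m": [2.0, 2.0, 2.0]})}}
        out = compare_zones(tables)
        assert out.loc["PI", "H"] == 0.0
        assert out.loc["PI", "p"] == 1.0

    def test_disjoint_ranges_significant(self):
        rng = np.random.default_rng(7)
        tables = {"EF_Mn": {
            "A": _index_table({"m": rng.uniform(0, 1, 10)}),
            "B": _index_table({"m": rng.uniform(5, 6, 10)}),
        }}
        assert compare_zones(tables).loc["EF_Mn", "p"] < 0.05

    def test_null_p_values_are_uniform(self):
        """KS check on 500 simulated null comparisons at alpha = 0.01."""
        from scipy import stats
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(500):
            g1, g2 = rng.normal(size=15), rng.normal(size=15)
            pvals.append(stats.kruskal(g1, g2).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
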