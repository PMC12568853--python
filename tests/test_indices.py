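"""Individual indices: values, class labels and their algebraic relations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roaddust import (
    ConcentrationMatrix,
    ReferenceSet,
    ValidationError,
    cf_from_zone_means,
    contamination_factor,
    enrichment_factor,
    igeo,
    pollution_index,
)
from roaddust.classification import SCHEMES


def _one_metal(conc_value: float, background: float) -> tuple:
    cm = ConcentrationMatrix(pd.DataFrame({"Cd": [conc_value]}, index=["S1"]))
    return cm, ReferenceSet(background={"Cd": background})


class TestIgeo:
    @pytest.mark.parametrize(
        "ratio,expected,label",
        [
            (1.5, 0.0, "unpolluted to moderately polluted"),
            (3.0, 1.0, "moderately polluted"),
            (48.0, 5.0, "extremely polluted"),  # log2(48/1.5) = log2(32)
            (1.0, np.log2(1 / 1.5), "unpolluted"),
        ],
    )
    def test_values_and_classes(self, ratio, expected, label):
        cm, ref = _one_metal(ratio * 2.0, 2.0)
        tab = igeo(cm, ref)
        assert tab.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert tab.classes.iloc[0, 0] == label

    def test_missing_background_names_metal(self, small_conc):
        with pytest.raises(ValidationError, match="Ni"):
            igeo(small_conc, ReferenceSet(background={"Cd": 1.0}))

    def test_negative_iff_below_one_and_a_half_background(self, small_conc, ref):
        tab = igeo(small_conc, ref)
        cb = pd.Series(ref.background)[small_conc.metals]
        below = small_conc.data < 1.5 * cb
        assert ((tab.values < 0) == below).all().all()


class TestPollutionIndex:
    @pytest.mark.parametrize(
        "ratio,label",
        [(1.0, "low"), (0.5, "none"), (5.0, "very accentuated"), (2.999, "moderate")],
    )
    def test_ratio_and_boundaries(self, ratio, label):
        cm, ref = _one_metal(ratio * 7.0, 7.0)
        tab = pollution_index(cm, ref)
        assert tab.values.iloc[0, 0] == pytest.approx(ratio)
        assert tab.classes.iloc[0, 0] == label

    def test_identity_with_igeo(self, small_conc, ref):
        """PI == 1.5 * 2**Igeo to 1e-12 relative, for any positive background."""
        pi = pollution_index(small_conc, ref).values
        ig = igeo(small_conc, ref).values
        np.testing.assert_allclose(pi, 1.5 * 2.0**ig, rtol=1e-12)

    @given(st.floats(0.05, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_concentration(self, factor):
        cm1, ref = _one_metal(3.0, 2.0)
        cm2, _ = _one_metal(3.0 * (1 + factor), 2.0)
        assert (
            pollution_index(cm2, ref).values.iloc[0, 0]
            > pollution_index(cm1, ref).values.iloc[0, 0]
        )


class TestEnrichmentFactor:
    def test_normalizer_metal_is_one(self, small_conc, ref):
        tab = enrichment_factor(small_conc, ref, normalizer="Mn")
        np.testing.assert_allclose(tab.values["Mn"], 1.0)
        assert tab.normalizer == "Mn"

    def test_background_proportional_sample_is_one_everywhere(self, ref):
        cb = pd.Series(ref.background)
        data = pd.DataFrame(
            [cb * 2.0, cb * 0.5], index=["S1", "S2"], columns=cb.index
        )
        tab = enrichment_factor(ConcentrationMatrix(data), ref, normalizer="Fe")
        np.testing.assert_allclose(tab.values, 1.0)

    def test_double_ratio_by_hand(self):
        # C_Cd/C_Mn twice the background ratio -> EF = 2, class moderate
        ref = ReferenceSet(background={"Cd": 1.0, "Mn": 100.0})
        data = pd.DataFrame({"Cd": [4.0, 8.0], "Mn": [200.0, 400.0]},
                            index=["S1", "S2"])
        tab = enrichment_factor(ConcentrationMatrix(data), ref, normalizer="Mn")
        np.testing.assert_allclose(tab.values["Cd"], 2.0)
        assert (tab.classes["Cd"] == "moderate").all()

    def test_invariant_to_per_site_rescaling(self, small_conc, ref):
        scaled = ConcentrationMatrix(
            small_conc.data.mul(
                pd.Series(np.linspace(0.2, 9.0, 12), index=small_conc.data.index),
                axis=0,
            )
        )
        a = enrichment_factor(small_conc, ref, normalizer="Mn").values
        b = enrichment_factor(scaled, ref, normalizer="Mn").values
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestContaminationFactor:
    def test_published_zone_means(self):
        from roaddust.datasets import KHOR_FAKKAN_MEAN
        tab = cf_from_zone_means(pd.Series(KHOR_FAKKAN_MEAN), ReferenceSet(), zone="KF")
        assert tab.values.loc["KF", "Cd"] == pytest.approx(33.219)
        assert tab.classes.loc["KF", "Cd"] == "very high"
        assert tab.values.loc["KF", "Mn"] == pytest.approx(233.667 / 850, abs=1e-6)
        assert tab.classes.loc["KF", "Mn"] == "low"

    def test_boundary_mean_equal_reference_is_moderate(self):
        tab = cf_from_zone_means(pd.Series({"Cd": 1.0}), ReferenceSet())
        assert tab.values.iloc[0, 0] == 1.0
        assert tab.classes.iloc[0, 0] == "moderate"

    def test_requires_five_sites(self, ref):
        data = pd.DataFrame({"Cd": [1.0, 2.0, 3.0, 4.0]},
                            index=[f"A{i}" for i in range(4)])
        with pytest.raises(ValidationError, match="five"):
            contamination_factor(ConcentrationMatrix(data), ref, "A")

    def test_metals_without_reference_are_excluded_with_warning(self, caplog):
        data = pd.DataFrame(
            {"Cd": np.full(5, 2.0), "Fe": np.full(5, 9000.0)},
            index=[f"A{i}" for i in range(5)],
        )
        with caplog.at_level("WARNING"):
            tab = contamination_factor(ConcentrationMatrix(data), ReferenceSet(), "A")
        assert list(tab.values.columns) == ["Cd"]
        assert "Fe" in caplog.text


class TestClassification:
    @pytest.mark.parametrize("scheme", ["Igeo", "PI", "EF", "CF", "PI_Nem"])
    def test_exhaustive_and_exclusive(self, scheme):
        s = SCHEMES[scheme]
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.uniform(-10, 60, 200), np.array(s.breakpoints, dtype=float)]
        )
        labels = s.classify(values)
        assert set(np.unique(labels)) <= set(s.labels)
        # each boundary value belongs to the interval it opens (left-closed)
        for b, expected in zip(s.breakpoints, s.labels[1:]):
            assert s.classify(np.array([b]))[0] == expected
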