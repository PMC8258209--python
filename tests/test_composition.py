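"""Volume estimation, %FO/%N/%V, IRI and the IRI-convention diagnostic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tepuidiet import (
    DietValidationError,
    IRIMode,
    compute_item_volumes,
    filter_analyzable,
    frequency_of_occurrence,
    implied_volume_feasibility,
    impute_fragment_volume,
    iri_table,
    numeric_percentage,
    prey_volume,
    volumetric_percentage,
)
from tepuidiet.composition import category_reference_dimensions

from conftest import build_dataset

NAN = np.nan

# Printed per-category %FO and %N for the O. quelchii population, the
# inputs of the IRI-convention diagnostic (categories in matching order:
# Acari, Coleoptera, Hemiptera excl. Het., Annelida, Araneae,
# Pseudoscorpionida, Diptera, Thysanoptera, Hymenoptera excl. Form.,
# Formicidae, Diplopoda, Chilopoda, Heteroptera).
QUELCHII_FO = np.array([55.7, 44.3, 18.2, 22.7, 15.9, 9.1, 6.8, 4.5, 4.5, 3.4, 3.4, 2.3, 1.1])
QUELCHII_N = np.array([36.5, 21.0, 11.4, 10.0, 6.4, 3.7, 3.2, 1.8, 1.8, 1.4, 1.4, 0.9, 0.5])


class TestPreyVolume:
    def test_zero_dimension_gives_zero_volume(self):
        assert prey_volume(0.0, 0.0) == 0.0
        assert prey_volume(2.0, 0.0) == 0.0

    def test_sphere_limit(self):
        # L = W = 1 is a sphere of diameter 1: V = pi/6
        assert prey_volume(1.0, 1.0) == pytest.approx(math.pi / 6, abs=1e-12)

    def test_prolate_spheroid(self):
        # L = 5, W = 2: (4 pi / 3) * 2.5 * 1 = 10 pi / 3
        assert prey_volume(5.0, 2.0) == pytest.approx(10 * math.pi / 3, abs=1e-12)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(DietValidationError):
            prey_volume(-1.0, 0.5)
        with pytest.raises(DietValidationError):
            prey_volume(1.0, 2.0)


class TestFragmentImputation:
    def _dataset_with_fragment(self):
        return build_dataset(
            [("s1", "sp", "male"), ("s2", "sp", "female")],
            [
                ("s1", "Coleoptera", 2.0, 1.0, True, False),
                ("s1", "Coleoptera", 2.0, 1.0, True, False),
                ("s2", "Coleoptera", 2.0, NAN, True, True),  # fragmented, W missing
            ],
        )

    def test_missing_width_imputed_from_intact_mean(self):
        ds = self._dataset_with_fragment()
        ref = category_reference_dimensions(ds)
        assert ref.loc["Coleoptera", "mean_width_mm"] == 1.0
        item = ds.prey.iloc[2]
        # imputed W = 1.0 -> V = (4 pi / 3) * 1 * 0.25
        assert impute_fragment_volume(item, ref) == pytest.approx(
            (4 * math.pi / 3) * 1.0 * 0.25, abs=1e-9
        )

    def test_fully_measured_fragment_equals_plain_volume(self):
        ds = self._dataset_with_fragment()
        ref = category_reference_dimensions(ds)
        item = ds.prey.iloc[0]
        assert impute_fragment_volume(item, ref) == prey_volume(2.0, 1.0)

    def test_no_reference_names_the_category(self):
        ds = build_dataset(
            [("s1", "sp", "male")],
            [("s1", "Araneae", NAN, NAN, True, True)],
        )
        ref = category_reference_dimensions(ds)
        with pytest.raises(DietValidationError, match="Araneae"):
            impute_fragment_volume(ds.prey.iloc[0], ref)

    def test_user_reference_table_fills_the_gap(self):
        ds = build_dataset(
            [("s1", "sp", "male")],
            [("s1", "Araneae", NAN, NAN, True, True)],
        )
        user_ref = pd.DataFrame(
            {"mean_length_mm": [1.5], "mean_width_mm": [0.8]}, index=["Araneae"]
        )
        vols = compute_item_volumes(ds, reference=user_ref)
        assert vols.iloc[0] == pytest.approx(prey_volume(1.5, 0.8))

    def test_unmeasured_intact_items_excluded_from_volume_with_warning(self):
        ds = build_dataset(
            [("s1", "sp", "male")],
            [
                ("s1", "Acari", 0.5, 0.3, True, False),
                ("s1", "Acari", NAN, NAN, True, False),  # identifiable, unmeasured
            ],
        )
        with pytest.warns(UserWarning, match="excluded"):
            vols = compute_item_volumes(ds)
        assert vols.notna().sum() == 1
        # still counts for %N
        assert numeric_percentage(ds, "Acari") == 100.0


class TestPercentages:
    def test_frequency_counts_stomachs_once(self, small_dataset):
        filtered, _ = filter_analyzable(small_dataset)
        # Acari in s1 (twice) and s3 -> 2 of 3 stomachs
        assert frequency_of_occurrence(filtered, "Acari") == pytest.approx(200 / 3)
        assert frequency_of_occurrence(filtered, "Thysanoptera") == 0.0

    def test_numeric_percentage_direct_count(self):
        ds = build_dataset(
            [("s1", "sp", "male")],
            [("s1", "Acari", 0.5, 0.3, True, False)] * 4
            + [("s1", "Coleoptera", 2.0, 1.0, True, False)] * 6,
        )
        assert numeric_percentage(ds, "Acari") == pytest.approx(40.0)
        assert numeric_percentage(ds, "Coleoptera") == pytest.approx(60.0)

    def test_single_category_is_one_hundred_percent(self):
        ds = build_dataset(
            [("s1", "sp", "male")],
            [("s1", "Acari", 0.5, 0.3, True, False)],
        )
        assert numeric_percentage(ds, "Acari") == 100.0

    def test_volumetric_ratio(self):
        # volumes 3 : 1 via sphere radii scaled accordingly
        l_big = (6 * 3.0 / math.pi) ** (1 / 3)
        l_small = (6 * 1.0 / math.pi) ** (1 / 3)
        ds = build_dataset(
            [("s1", "sp", "male")],
            [
                ("s1", "Acari", l_big, l_big, True, False),
                ("s1", "Coleoptera", l_small, l_small, True, False),
            ],
        )
        assert volumetric_percentage(ds, "Acari") == pytest.approx(75.0)
        assert volumetric_percentage(ds, "Coleoptera") == pytest.approx(25.0)

    def test_identical_volumes_make_v_equal_n(self, small_dataset):
        filtered, _ = filter_analyzable(small_dataset)
        uniform = filtered.copy()
        uniform.prey["length_mm"] = 1.0
        uniform.prey["width_mm"] = 1.0
        for cat in uniform.prey["category"].unique():
            assert volumetric_percentage(uniform, cat) == pytest.approx(
                numeric_percentage(uniform, cat)
            )

    def test_volume_scale_invariance(self, small_dataset):
        filtered, _ = filter_analyzable(small_dataset)
        scaled = filtered.copy()
        scaled.prey["length_mm"] *= 3.0
        scaled.prey["width_mm"] *= 3.0
        for cat in filtered.prey["category"].unique():
            assert volumetric_percentage(scaled, cat) == pytest.approx(
                volumetric_percentage(filtered, cat)
            )

    def test_empty_denominators_are_errors(self):
        ds = build_dataset([("s1", "sp", "male")], [])
        with pytest.raises(DietValidationError):
            frequency_of_occurrence(ds, "Acari")
        with pytest.raises(DietValidationError):
            numeric_percentage(ds, "Acari")


def _two_category_dataset():
    """FO 100/50, N 60/40, V 70/30 across two stomachs.

    Ten items: six of category A (three per stomach) and four of B (all
    in stomach 1); per-item sphere sizes chosen so A's summed volume is
    7 and B's is 3.
    """
    def sphere_l(v):
        return (6 * v / math.pi) ** (1 / 3)

    la, lb = sphere_l(7 / 6), sphere_l(3 / 4)
    rows = []
    for sid, cat, l, k in [("s1", "Acari", la, 3), ("s2", "Acari", la, 3),
                           ("s1", "Coleoptera", lb, 4)]:
        rows += [(sid, cat, l, l, True, False)] * k
    return build_dataset([("s1", "sp", "male"), ("s2", "sp", "female")], rows)


class TestIRITable:
    def test_multiplicative_hand_oracle(self):
        # IRI_A = 100*(60+70) = 13000, IRI_B = 50*(40+30) = 3500
        # %IRI_A = 13000/16500 = 78.79
        metrics = {m.category: m for m in iri_table(_two_category_dataset())}
        a, b = metrics["Acari"], metrics["Coleoptera"]
        assert a.FO_pct == pytest.approx(100.0)
        assert a.N_pct == pytest.approx(60.0)
        assert a.V_pct == pytest.approx(70.0)
        assert a.IRI == pytest.approx(13000.0)
        assert b.IRI == pytest.approx(3500.0)
        assert a.IRI_pct == pytest.approx(100 * 13000 / 16500)

    def test_additive_hand_oracle(self):
        # IRI_A = 100+130 = 230, IRI_B = 50+70 = 120; %IRI_A = 230/350
        metrics = {
            m.category: m
            for m in iri_table(_two_category_dataset(), mode=IRIMode.ADDITIVE_AS_PRINTED)
        }
        assert metrics["Acari"].IRI == pytest.approx(230.0)
        assert metrics["Coleoptera"].IRI == pytest.approx(120.0)
        assert metrics["Acari"].IRI_pct == pytest.approx(100 * 230 / 350)

    @pytest.mark.parametrize("mode", list(IRIMode))
    def test_single_category_normalizes_to_one_hundred(self, mode):
        ds = build_dataset(
            [("s1", "sp", "male")],
            [("s1", "Acari", 0.5, 0.3, True, False)],
        )
        (only,) = iri_table(ds, mode=mode)
        assert only.IRI_pct == pytest.approx(100.0)

    @pytest.mark.parametrize("mode", list(IRIMode))
    @given(seed=st.integers(0, 2**31 - 1))
    def test_percentage_normalization_property(self, mode, seed):
        from tepuidiet import default_config, generate_dataset

        # fully measured items: rare categories may otherwise consist
        # solely of fragments, which (correctly) demand a reference table
        cfg = default_config("quelchii").model_copy(update={"fragment_prob": 0.0})
        ds = generate_dataset(cfg, seed=seed)
        filtered, _ = filter_analyzable(ds)
        metrics = iri_table(filtered, mode=mode)
        assert sum(m.N_pct for m in metrics) == pytest.approx(100.0, abs=1e-9)
        assert sum(m.V_pct for m in metrics) == pytest.approx(100.0, abs=1e-9)
        assert sum(m.IRI_pct for m in metrics) == pytest.approx(100.0, abs=1e-9)

    def test_row_order_does_not_matter(self, small_dataset):
        filtered, _ = filter_analyzable(small_dataset)
        shuffled = filtered.copy()
        shuffled.prey = shuffled.prey.sample(frac=1, random_state=0).reset_index(drop=True)
        a = {m.category: m for m in iri_table(filtered)}
        b = {m.category: m for m in iri_table(shuffled)}
        for cat in a:
            assert a[cat].IRI_pct == pytest.approx(b[cat].IRI_pct)

    def test_adding_an_item_raises_n_and_never_lowers_fo(self, small_dataset):
        filtered, _ = filter_analyzable(small_dataset)
        before_n = numeric_percentage(filtered, "Coleoptera")
        before_fo = frequency_of_occurrence(filtered, "Coleoptera")
        grown = filtered.copy()
        grown.prey = pd.concat(
            [grown.prey, grown.prey.iloc[[2]].assign(specimen_id="s3")],
            ignore_index=True,
        )
        assert numeric_percentage(grown, "Coleoptera") > before_n
        assert frequency_of_occurrence(grown, "Coleoptera") >= before_fo


class TestIRIConventionDiagnostic:
    """The printed %IRI values identify the convention actually used.

    Feeding the printed per-category %FO and %N values together with the
    two printed %IRI shares (Acari 40.9, Coleoptera 42.5) into the
    linear feasibility check shows that no non-negative volumetric
    composition summing to 100 can produce those shares under the
    additive convention -- the two implied %V values alone exceed 100 --
    while the multiplicative convention admits a feasible composition.
    """

    TARGETS = {0: 40.9, 1: 42.5}

    def test_additive_convention_is_arithmetically_impossible(self):
        res = implied_volume_feasibility(
            QUELCHII_FO, QUELCHII_N, self.TARGETS, IRIMode.ADDITIVE_AS_PRINTED
        )
        assert not res["feasible"]
        implied = res["implied_v"]
        assert sum(implied.values()) > 100.0
        # the Coleoptera share alone needs more than the whole volume
        assert implied[1] > 100.0

    def test_multiplicative_convention_is_consistent(self):
        res = implied_volume_feasibility(
            QUELCHII_FO, QUELCHII_N, self.TARGETS, IRIMode.MULTIPLICATIVE
        )
        assert res["feasible"]
        v = res["v"]
        assert v.sum() == pytest.approx(100.0, abs=1e-6)
        assert (v >= -1e-9).all()
        iri = QUELCHII_FO * (QUELCHII_N + v)
        shares = 100 * iri / iri.sum()
        assert shares[0] == pytest.approx(40.9, abs=1e-6)
        assert shares[1] == pytest.approx(42.5, abs=1e-6)
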