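import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbsheets.balance import (
    CerealSplitSpec,
    FlowRecord,
    aggregate_country,
    apply_processing_factor,
    compute_nutrients,
    split_cereal_flours,
    to_per_capita,
)
from nbsheets.food_model import FoodCategory, Taxonomy


class TestToPerCapita:
    def test_annual_tonnage_to_daily_grams(self):
        # 36.5 thousand MT/yr over 1M people = 100 g/person/day
        assert to_per_capita(36.5, 1_000_000) == pytest.approx(100.0)

    def test_zero_quantity(self):
        assert to_per_capita(0.0, 5_000) == 0.0

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError):
            to_per_capita(1.0, 0)

    def test_flow_record_rejects_negative_nonstock(self):
        with pytest.raises(ValueError):
            FlowRecord("A", 2000, "wheat", "food", -1.0)
        FlowRecord("A", 2000, "wheat", "stock_change", -1.0)  # allowed


class TestCerealSplit:
    def test_wheat_straight_grade_split(self):
        spec = CerealSplitSpec("wheat", "r", 0.8, 0.72, 1.0)
        refined, whole = split_cereal_flours(100.0, spec)
        assert refined == pytest.approx(57.6)
        assert whole == pytest.approx(20.0)

    def test_all_whole_grain(self):
        spec = CerealSplitSpec("wheat", "r", 0.0, 0.72, 1.0)
        assert split_cereal_flours(100.0, spec) == (0.0, 100.0)

    def test_all_refined_maize(self):
        spec = CerealSplitSpec("maize", "r", 1.0, 0.70, 1.0)
        refined, whole = split_cereal_flours(100.0, spec)
        assert refined == pytest.approx(70.0)
        assert whole == 0.0

    @given(
        grain=st.floats(0, 1e4),
        p=st.floats(0, 1),
        e_r=st.floats(0.01, 1),
        e_w=st.floats(0.01, 1),
    )
    def test_split_conserves_pre_extraction_grain(self, grain, p, e_r, e_w):
        spec = CerealSplitSpec("c", "r", p, e_r, e_w)
        refined, whole = split_cereal_flours(grain, spec)
        assert refined / e_r + whole / e_w == pytest.approx(grain, rel=1e-9, abs=1e-9)

    def test_out_of_range_proportion_rejected(self):
        with pytest.raises(ValueError):
            CerealSplitSpec("wheat", "r", 1.2, 0.72, 1.0)


class TestProcessingFactor:
    @pytest.mark.parametrize(
        "mass,factor,expected",
        [(10.0, 0.11, 1.1), (1.0, 119.05, 119.05), (42.0, 1.0, 42.0)],
    )
    def test_factor_arithmetic(self, mass, factor, expected):
        assert apply_processing_factor(mass, factor) == pytest.approx(expected)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            apply_processing_factor(1.0, 0.0)


class TestComputeNutrients:
    COMP = pd.Series({"iron": 2.0})

    def test_beef_iron_processing_only(self):
        # 200 g/day at 33.3% refuse and 2 mg iron/100 g
        v = compute_nutrients(200.0, 0.333, 1.0, self.COMP, "processing_only")
        assert v["iron"] == pytest.approx(2.668, rel=1e-12)

    def test_final_best_adds_flw_and_cooking(self):
        flw = (1 - 0.05) * (1 - 0.11)
        v = compute_nutrients(
            200.0, 0.333, 1.0, self.COMP, "final_best",
            flw_retention=flw, cooking_retention=0.90,
        )
        assert v["iron"] == pytest.approx(2.668 * 0.95 * 0.89 * 0.90, rel=1e-12)

    def test_exempt_fsg_final_best_is_processing_times_cooking(self):
        base = compute_nutrients(50.0, 0.0, 0.9, self.COMP, "processing_only")
        fb = compute_nutrients(
            50.0, 0.0, 0.9, self.COMP, "final_best",
            flw_retention=1.0, cooking_retention=0.8,
        )
        assert fb["iron"] == pytest.approx(base["iron"] * 0.8, rel=1e-12)

    @given(
        g=st.floats(0, 1e4),
        scale=st.floats(0.01, 100),
        refuse=st.floats(0, 0.99),
        flw=st.floats(0, 1),
        cook=st.floats(0, 1),
    )
    def test_homogeneous_degree_one_in_quantity(self, g, scale, refuse, flw, cook):
        kw = dict(
            refuse_fraction=refuse,
            processing_retention=0.9,
            composition_per_100g=self.COMP,
            variant="final_best",
            flw_retention=flw,
            cooking_retention=cook,
        )
        a = compute_nutrients(g, **kw)["iron"]
        b = compute_nutrients(g * scale, **kw)["iron"]
        assert b == pytest.approx(a * scale, rel=1e-9, abs=1e-12)

    @given(
        g=st.floats(0, 1e4),
        refuse=st.floats(0, 0.99),
        proc=st.floats(0.01, 1.0),
        flw=st.floats(0, 1),
        cook=st.floats(0, 1),
    )
    def test_final_best_never_exceeds_processing_only(self, g, refuse, proc, flw, cook):
        kw = dict(
            refuse_fraction=refuse,
            processing_retention=proc,
            composition_per_100g=self.COMP,
        )
        fb = compute_nutrients(
            g, variant="final_best", flw_retention=flw, cooking_retention=cook, **kw
        )["iron"]
        po = compute_nutrients(g, variant="processing_only", **kw)["iron"]
        assert fb <= po + 1e-12 * max(po, 1.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_nutrients(-1.0, 0.0, 1.0, self.COMP, "raw")


class TestAggregateCountry:
    def _table(self):
        rows = []
        for fc, element, value in [
            ("wheat", "production", 5.0),
            ("palm_oil", "production", 9.0),
            ("wheat", "food", 3.0),
            ("palm_oil", "food", 2.0),
        ]:
            rows.append(
                {
                    "country": "A", "year": 2000, "fc_code": fc, "source_fc": fc,
                    "element": element, "variant": "final_best",
                    "nutrient": "energy", "value": value,
                }
            )
        return pd.DataFrame(rows)

    def _taxonomy(self):
        return Taxonomy(
            [
                FoodCategory("wheat", "Wheat", "cereals", "starchy_staples"),
                FoodCategory(
                    "palm_oil", "Palm oil", "vegetable_oils", "other",
                    is_processed_food=True,
                ),
            ]
        )

    def test_production_excludes_processed_foods(self):
        out = aggregate_country(self._table(), "production", self._taxonomy())
        assert out["value"].tolist() == [5.0]

    def test_intake_counts_all_fcs(self):
        out = aggregate_country(self._table(), "apparent_intake", self._taxonomy())
        assert out["value"].tolist() == [5.0]  # 3 + 2

    def test_empty_side_warns_and_returns_empty(self):
        table = self._table()
        table = table[table["element"] == "food"]
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out = aggregate_country(table, "production", self._taxonomy())
        assert out.empty
        assert any("no rows" in str(w.message) for w in rec)
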