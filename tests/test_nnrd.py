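import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbsheets.nnrd import (
    PregnancyDurations,
    ReproductiveStats,
    estimate_lactating,
    estimate_pregnant,
    infants_0_5_months,
    reallocate_reproductive,
    weighted_requirement,
)


def drv_rows(nutrient, values, value_type="AR", basis="absolute_per_day"):
    """(child, adult M, adult F, pregnant, lactating) DRV rows."""
    groups = [
        (0, 14, "any", False, False),
        (15, 100, "M", False, False),
        (15, 100, "F", False, False),
        (0, 100, "F", True, False),
        (0, 100, "F", False, True),
    ]
    return pd.DataFrame(
        [
            {
                "nutrient": nutrient, "age_min": a0, "age_max": a1, "sex": sex,
                "pregnant": p, "lactating": l, "value_type": value_type,
                "value": v, "basis": basis,
            }
            for (a0, a1, sex, p, l), v in zip(groups, values)
        ]
    )


def cells(rows):
    df = pd.DataFrame(rows, columns=["age", "sex", "count"])
    df["pregnant"] = False
    df["lactating"] = False
    return df


class TestPregnancyEstimates:
    def test_all_zero(self):
        assert estimate_pregnant(ReproductiveStats(0, 0, 0)) == 0.0

    def test_duration_weighting(self):
        d = PregnancyDurations(d_birth=0.75, d_abortion=0.0, d_miscarriage=0.0)
        assert estimate_pregnant(ReproductiveStats(1000, 500, 500), d) == pytest.approx(750)

    @given(
        births=st.floats(0, 1e6),
        abortions=st.floats(0, 1e5),
        miscarriages=st.floats(0, 1e5),
    )
    def test_linearity(self, births, abortions, miscarriages):
        s1 = ReproductiveStats(births, abortions, miscarriages)
        s2 = ReproductiveStats(2 * births, 2 * abortions, 2 * miscarriages)
        assert estimate_pregnant(s2) == pytest.approx(2 * estimate_pregnant(s1), rel=1e-12)

    def test_lactating_is_six_months_of_births(self):
        assert estimate_lactating(1_000_000) == pytest.approx(500_000)
        assert estimate_lactating(0) == 0.0

    def test_infants_equal_lactating_mothers(self):
        assert infants_0_5_months(1_000_000) == estimate_lactating(1_000_000)


class TestReallocation:
    def test_total_population_conserved(self):
        base = cells([(30, "F", 1000), (30, "M", 1000), (8, "F", 500)])
        out = reallocate_reproductive(base[["age", "sex", "count"]], 60, 40)
        assert out["count"].sum() == pytest.approx(2500)
        assert out[out["pregnant"]]["count"].iloc[0] == 60
        assert out[out["lactating"]]["count"].iloc[0] == 40

    def test_draws_only_from_reproductive_age_females(self):
        base = cells([(30, "F", 1000), (70, "F", 800)])
        out = reallocate_reproductive(base[["age", "sex", "count"]], 100, 0)
        old = out[(out["age"] == 70) & ~out["pregnant"] & ~out["lactating"]]
        assert old["count"].iloc[0] == 800

    def test_overdraw_rejected(self):
        base = cells([(30, "F", 10)])
        with pytest.raises(ValueError, match="exceeds"):
            reallocate_reproductive(base[["age", "sex", "count"]], 100, 0)


class TestWeightedRequirement:
    def test_single_group_identity(self):
        drvs = drv_rows("vitamin_a", [300, 570, 490, 540, 1020])
        req, used = weighted_requirement(cells([(30, "M", 500)]), drvs, "vitamin_a")
        assert req == pytest.approx(570)
        assert used == "AR"

    def test_weighted_mean_of_two_groups(self):
        drvs = drv_rows("x", [700, 700, 900, 900, 900])
        c = cells([(8, "M", 100), (30, "F", 300)])
        req, _ = weighted_requirement(c, drvs, "x")
        assert req == pytest.approx((100 * 700 + 300 * 900) / 400)

    def test_protein_per_kg_body_weight(self):
        drvs = drv_rows("protein", [1.0] * 5, basis="per_kg_bodyweight")
        bw = pd.DataFrame(
            [{"age_min": 0, "age_max": 100, "sex": "any", "weight_kg": 70.0}]
        )
        req, _ = weighted_requirement(
            cells([(30, "M", 10)]), drvs, "protein", body_weights=bw
        )
        assert req == pytest.approx(70.0)

    def test_ai_fallback_when_no_ar(self):
        drvs = drv_rows("vitamin_c", [40, 90, 80, 95, 140], value_type="AI")
        _, used = weighted_requirement(cells([(30, "M", 1)]), drvs, "vitamin_c")
        assert used == "AI"

    def test_unmatched_cell_errors_listing_group(self):
        drvs = drv_rows("x", [1, 2, 3, 4, 5])
        drvs = drvs[drvs["sex"] != "M"]  # remove the adult-male group
        with pytest.raises(ValueError, match="sex=M"):
            weighted_requirement(cells([(30, "M", 10)]), drvs, "x")

    def test_requirement_within_group_drv_range(self):
        drvs = drv_rows("x", [100, 200, 300, 400, 500])
        c = cells([(8, "F", 50), (30, "M", 70), (30, "F", 80)])
        alloc = reallocate_reproductive(c[["age", "sex", "count"]], 5, 5)
        req, _ = weighted_requirement(alloc, drvs, "x")
        assert 100 <= req <= 500

    @given(split=st.floats(0.01, 0.99))
    def test_invariant_to_splitting_a_cell(self, split):
        drvs = drv_rows("x", [100, 200, 300, 400, 500])
        whole = cells([(30, "M", 1000)])
        parts = cells([(30, "M", 1000 * split), (40, "M", 1000 * (1 - split))])
        r1, _ = weighted_requirement(whole, drvs, "x")
        r2, _ = weighted_requirement(parts, drvs, "x")
        assert r1 == pytest.approx(r2, rel=1e-12)
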