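import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbsheets.bioavailability import (
    IRON_ALGORITHMS,
    DietProfile,
    absorbed_zinc,
    default_params,
    nonheme_bioavailability,
    percent_absorbed_zinc,
    split_heme,
    total_bioavailable_iron,
)

PARAMS = default_params()

REFERENCE_PROFILE = DietProfile(
    nonheme_iron=12.0,
    heme_iron=1.5,
    zinc=9.8,
    phytate=990.0,
    calcium=800.0,
    vitamin_c=50.0,
    mfp=120.0,
    polyphenols=60.0,
    energy=2400.0,
    protein=70.0,
)


def hand_eval(profile: DietProfile, algorithm: str) -> float:
    """Independent re-evaluation of the parameter file, written from scratch."""
    spec = PARAMS.config["iron_algorithms"][algorithm]
    cov = {
        "nonheme_iron": profile.nonheme_iron,
        "vitamin_c": profile.vitamin_c,
        "mfp": profile.mfp,
        "phytate": profile.phytate,
        "calcium": profile.calcium,
        "polyphenols": profile.polyphenols,
        "tea_cups": profile.polyphenols / PARAMS.polyphenol_mg_per_cup,
        "serum_ferritin": PARAMS.serum_ferritin_ref,
    }
    if spec["form"] == "loglinear":
        s = spec["intercept"]
        for t in spec["terms"]:
            x = cov[t["covariate"]] + t.get("offset", 0.0)
            s += t["coefficient"] * (math.log(x) if t["transform"] == "log" else x)
        v = math.exp(s)
    else:
        num = 1.0 + sum(
            e["amplitude"] * cov[e["covariate"]] / (cov[e["covariate"]] + e["half_saturation"])
            for e in spec["enhancers"]
        )
        den = 1.0 + sum(
            e["amplitude"] * cov[e["covariate"]] / (cov[e["covariate"]] + e["half_saturation"])
            for e in spec["inhibitors"]
        )
        v = spec["baseline_fraction"] * num / den
    if spec.get("output") == "percent":
        v /= 100.0
    return min(max(v, 1e-3), 1.0)


class TestSplitHeme:
    def test_forty_percent_of_hsi_iron_is_heme(self):
        heme, nonheme = split_heme(
            {"beef": 3.0, "spinach": 5.0}, {"beef": True, "spinach": False}
        )
        assert heme == pytest.approx(1.2)
        assert nonheme == pytest.approx(6.8)

    def test_no_hsi_foods(self):
        heme, nonheme = split_heme({"rice": 4.0}, {"rice": False})
        assert heme == 0.0
        assert nonheme == 4.0

    def test_all_hsi_diet(self):
        heme, nonheme = split_heme({"beef": 10.0}, {"beef": True})
        assert heme == pytest.approx(4.0)
        assert nonheme == pytest.approx(6.0)


class TestNonhemeAlgorithms:
    @pytest.mark.parametrize("algorithm", IRON_ALGORITHMS)
    def test_matches_independent_hand_evaluation(self, algorithm):
        got = nonheme_bioavailability(REFERENCE_PROFILE, algorithm, PARAMS)
        assert got == pytest.approx(hand_eval(REFERENCE_PROFILE, algorithm), rel=1e-12)

    @pytest.mark.parametrize("algorithm", IRON_ALGORITHMS)
    def test_fraction_in_valid_range(self, algorithm):
        f = nonheme_bioavailability(REFERENCE_PROFILE, algorithm, PARAMS)
        assert 0.001 <= f <= 1.0

    @pytest.mark.parametrize("algorithm", IRON_ALGORITHMS)
    @given(p1=st.floats(0, 3000), p2=st.floats(0, 3000))
    def test_phytate_never_increases_absorption(self, algorithm, p1, p2):
        lo, hi = sorted([p1, p2])
        f_lo = nonheme_bioavailability(
            DietProfile(nonheme_iron=10, vitamin_c=30, mfp=50, phytate=lo, calcium=500),
            algorithm, PARAMS,
        )
        f_hi = nonheme_bioavailability(
            DietProfile(nonheme_iron=10, vitamin_c=30, mfp=50, phytate=hi, calcium=500),
            algorithm, PARAMS,
        )
        assert f_hi <= f_lo + 1e-12

    @pytest.mark.parametrize("algorithm", IRON_ALGORITHMS)
    @given(c1=st.floats(0, 500), c2=st.floats(0, 500))
    def test_vitamin_c_effect_non_negative(self, algorithm, c1, c2):
        lo, hi = sorted([c1, c2])
        base = DietProfile(nonheme_iron=10, mfp=50, phytate=800, calcium=500)
        f_lo = nonheme_bioavailability(
            DietProfile(**{**base.__dict__, "vitamin_c": lo}), algorithm, PARAMS
        )
        f_hi = nonheme_bioavailability(
            DietProfile(**{**base.__dict__, "vitamin_c": hi}), algorithm, PARAMS
        )
        assert f_hi >= f_lo - 1e-12

    def test_zero_nonheme_iron_yields_zero_bioavailable(self):
        profile = DietProfile(nonheme_iron=0.0, vitamin_c=50, phytate=500)
        for algorithm in IRON_ALGORITHMS:
            f = nonheme_bioavailability(profile, algorithm, PARAMS)
            res = total_bioavailable_iron(0.0, 0.0, f)
            assert res.bioavailable_nonheme == 0.0

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown iron algorithm"):
            nonheme_bioavailability(REFERENCE_PROFILE, "magic", PARAMS)


class TestTotalBioavailableIron:
    def test_heme_25pct_plus_nonheme_fraction(self):
        res = total_bioavailable_iron(1.2, 10.0, 0.15)
        assert res.bioavailable_heme == pytest.approx(0.30)
        assert res.bioavailable_nonheme == pytest.approx(1.50)
        assert res.total_bioavailable == pytest.approx(1.80)
        assert res.percent_bioavailability == pytest.approx(100 * 1.80 / 11.2)

    def test_zero_nonheme_fraction(self):
        res = total_bioavailable_iron(4.0, 6.0, 0.0)
        assert res.total_bioavailable == pytest.approx(1.0)

    def test_zero_diet_percent_is_missing(self):
        res = total_bioavailable_iron(0.0, 0.0, 0.2)
        assert res.total_bioavailable == 0.0
        assert math.isnan(res.percent_bioavailability)

    @given(
        heme=st.floats(0, 10),
        nonheme=st.floats(0, 30),
        frac=st.floats(0.001, 1.0),
    )
    def test_never_exceeds_total_intake(self, heme, nonheme, frac):
        res = total_bioavailable_iron(heme, nonheme, frac)
        assert res.total_bioavailable <= heme + nonheme + 1e-12

    @given(scale=st.floats(0.1, 50))
    def test_percent_invariant_under_uniform_scaling(self, scale):
        a = total_bioavailable_iron(1.2, 10.0, 0.15)
        b = total_bioavailable_iron(1.2 * scale, 10.0 * scale, 0.15)
        assert b.percent_bioavailability == pytest.approx(
            a.percent_bioavailability, rel=1e-9
        )


class TestAbsorbedZinc:
    def test_zero_zinc_gives_zero(self):
        assert absorbed_zinc(0.0, 500.0, PARAMS) == 0.0

    def test_saturation_limit_without_phytate(self):
        # TDZ >> Amax: absorption saturates at Amax (in mg).
        amax_mg = PARAMS.miller_amax * PARAMS.zinc_molar_mass
        taz = absorbed_zinc(10_000.0, 0.0, PARAMS)
        assert taz == pytest.approx(amax_mg, rel=1e-3)

    def test_closed_form_matches_numeric_root(self):
        # Independent oracle: TAZ is the smaller root of
        # t^2 - A t + Amax*TDZ = 0; solve numerically via np.roots.
        zinc, phytate = 9.8, 990.0
        tdz = zinc / PARAMS.zinc_molar_mass
        tdp = phytate / PARAMS.phytate_molar_mass
        a = PARAMS.miller_amax + tdz + PARAMS.miller_kr * (1 + tdp / PARAMS.miller_kp)
        roots = np.roots([1.0, -a, PARAMS.miller_amax * tdz])
        expected = min(roots.real) * PARAMS.zinc_molar_mass
        assert absorbed_zinc(zinc, phytate, PARAMS) == pytest.approx(expected, rel=1e-9)

    @given(zinc=st.floats(0, 50), phytate=st.floats(0, 5000))
    def test_taz_bounded_by_amax_and_intake(self, zinc, phytate):
        taz = absorbed_zinc(zinc, phytate, PARAMS)
        amax_mg = PARAMS.miller_amax * PARAMS.zinc_molar_mass
        assert -1e-12 <= taz <= min(amax_mg, zinc) + 1e-9

    @given(z1=st.floats(0.1, 50), z2=st.floats(0.1, 50), phytate=st.floats(0, 5000))
    def test_taz_increasing_in_zinc(self, z1, z2, phytate):
        lo, hi = sorted([z1, z2])
        assert absorbed_zinc(hi, phytate, PARAMS) >= absorbed_zinc(lo, phytate, PARAMS) - 1e-12

    @given(p1=st.floats(0, 5000), p2=st.floats(0, 5000), zinc=st.floats(0.1, 50))
    def test_taz_decreasing_in_phytate(self, p1, p2, zinc):
        lo, hi = sorted([p1, p2])
        assert absorbed_zinc(zinc, hi, PARAMS) <= absorbed_zinc(zinc, lo, PARAMS) + 1e-12

    def test_percent_absorbed_zero_supply_missing(self):
        assert math.isnan(percent_absorbed_zinc(0.0, 100.0, PARAMS))
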