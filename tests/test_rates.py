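import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefcast.community import ParrotfishRecord, TransectState
from reefcast.errors import ConfigurationError, InvalidParameterError
from reefcast.rates import (
    DEFAULT_REFERENCE_ENV,
    RateConfig,
    ResponseCurve,
    cca_production,
    coral_production,
    micro_erosion,
    parrotfish_erosion,
    response_multiplier,
    sand_dissolution,
    sponge_erosion,
    urchin_erosion,
)

REF_SST, REF_OMEGA = DEFAULT_REFERENCE_ENV
CFG = RateConfig()


def state_with(**overrides):
    base = dict(
        transect_id="T",
        coral_cover={},
        cca_cover=0.0,
        sand_cover=0.0,
        substrate_cover=0.0,
        rugosity=1.0,
    )
    base.update(overrides)
    return TransectState(**base)


class TestResponseMultiplier:
    def test_reference_environment_gives_exactly_one(self):
        for curve in CFG.curves.values():
            assert response_multiplier(curve, REF_SST, REF_OMEGA) == 1.0

    def test_additive_combination_by_hand(self):
        curve = ResponseCurve("x", temp_slope=-0.05, omega_slope=0.10, sst_ref=27, omega_ref=4)
        assert response_multiplier(curve, 29.0, 3.0) == pytest.approx(0.80)

    def test_collapse_below_omega_threshold(self):
        curve = ResponseCurve("cca", omega_slope=0.3, collapse_omega=2.0, omega_ref=4)
        assert response_multiplier(curve, REF_SST, 1.9) == 0.0

    def test_floor_applies(self):
        curve = ResponseCurve("x", temp_slope=-1.0, sst_ref=27)
        assert response_multiplier(curve, 40.0, REF_OMEGA) == 0.0


class TestCoralProduction:
    def test_full_cover_reference_rate(self):
        state = state_with(coral_cover={"Orbicella faveolata": 100.0})
        assert coral_production(state, CFG, REF_SST, REF_OMEGA) == pytest.approx(12.0)

    def test_zero_cover(self):
        assert coral_production(state_with(), CFG, REF_SST, REF_OMEGA) == 0.0

    def test_rugosity_scaling_hand_value(self):
        state = state_with(coral_cover={"Siderastrea siderea": 25.0}, rugosity=2.0)
        assert coral_production(state, CFG, REF_SST, REF_OMEGA) == pytest.approx(4.95)

    def test_missing_rate_rejected(self):
        state = state_with(coral_cover={"Unknownia species": 10.0})
        with pytest.raises(ConfigurationError):
            coral_production(state, CFG, REF_SST, REF_OMEGA)

    def test_missing_rate_uses_configured_fallback(self):
        cfg = dataclasses.replace(CFG, coral_fallback_rate=5.0)
        state = state_with(coral_cover={"Unknownia species": 10.0})
        assert coral_production(state, cfg, REF_SST, REF_OMEGA) == pytest.approx(0.5)

    @given(scale=st.floats(0.1, 3.0))
    def test_linear_in_cover(self, scale):
        base = state_with(coral_cover={"Orbicella faveolata": 10.0})
        scaled = state_with(coral_cover={"Orbicella faveolata": 10.0 * scale})
        assert coral_production(scaled, CFG, 28.0, 3.5) == pytest.approx(
            scale * coral_production(base, CFG, 28.0, 3.5)
        )


class TestCcaProduction:
    def test_full_cover_reference_rate(self):
        state = state_with(cca_cover=100.0)
        assert cca_production(state, CFG, REF_SST, REF_OMEGA) == pytest.approx(0.5)

    def test_collapse_below_omega(self):
        state = state_with(cca_cover=100.0)
        assert cca_production(state, CFG, REF_SST, 1.9) == 0.0

    def test_zero_cover(self):
        assert cca_production(state_with(), CFG, REF_SST, REF_OMEGA) == 0.0


class TestSpongeErosion:
    def test_zero_cover(self):
        assert sponge_erosion(state_with(), CFG, REF_SST, REF_OMEGA) == 0.0

    def test_full_cover_unit_conversion(self):
        cfg = dataclasses.replace(CFG, sponge_erosion_rates={"S": 5.0})
        state = state_with(sponge_cover={"S": 1e4})
        assert sponge_erosion(state, cfg, REF_SST, REF_OMEGA) == pytest.approx(5.0)

    def test_reference_env_multiplier_is_one(self):
        state = state_with(sponge_cover={"Cliona varians": 500.0})
        expected = (500.0 / 1e4) * CFG.sponge_erosion_rates["Cliona varians"]
        assert sponge_erosion(state, CFG, REF_SST, REF_OMEGA) == pytest.approx(expected)

    def test_rises_under_acidification(self):
        state = state_with(sponge_cover={"Cliona varians": 500.0})
        ref = sponge_erosion(state, CFG, REF_SST, REF_OMEGA)
        acid = sponge_erosion(state, CFG, REF_SST, REF_OMEGA - 1.0)
        assert acid > ref

    def test_unknown_species_rejected(self):
        state = state_with(sponge_cover={"Mystery sponge": 100.0})
        with pytest.raises(ConfigurationError):
            sponge_erosion(state, CFG, REF_SST, REF_OMEGA)


class TestParrotfishErosion:
    def test_empty_census(self):
        assert parrotfish_erosion(state_with(), CFG) == 0.0

    def test_hand_value(self):
        cfg = dataclasses.replace(
            CFG, parrotfish_bite={("P", "initial", "15-24"): 2.5}, parrotfish_survey_area_m2=120.0
        )
        state = state_with(parrotfish_census=(ParrotfishRecord("P", "initial", "15-24", 12),))
        assert parrotfish_erosion(state, cfg) == pytest.approx(0.25)

    def test_unknown_size_class_rejected(self):
        state = state_with(parrotfish_census=(ParrotfishRecord("P", "initial", "99", 1),))
        with pytest.raises(ConfigurationError):
            parrotfish_erosion(state, CFG)


class TestUrchinErosion:
    def test_no_urchins(self):
        assert urchin_erosion(state_with(), CFG) == 0.0

    def test_hand_value(self):
        cfg = dataclasses.replace(
            CFG, urchin_rate_params={"U": (0.4, 0.0)}, urchin_survey_area_m2=20.0
        )
        state = state_with(urchin_sizes={"U": (1.0,) * 5})
        assert urchin_erosion(state, cfg) == pytest.approx(0.1)

    def test_doubling_counts_doubles_result(self):
        one = state_with(urchin_sizes={"Echinometra": (3.0, 4.0)})
        two = state_with(urchin_sizes={"Echinometra": (3.0, 4.0, 3.0, 4.0)})
        assert urchin_erosion(two, CFG) == pytest.approx(2 * urchin_erosion(one, CFG))


class TestMicroErosion:
    def test_full_substrate_reference_rate(self):
        state = state_with(substrate_cover=100.0)
        assert micro_erosion(state, CFG, REF_SST, REF_OMEGA) == pytest.approx(0.240)

    def test_zero_substrate(self):
        assert micro_erosion(state_with(), CFG, REF_SST, REF_OMEGA) == 0.0

    def test_multiplier_scaling_hand_value(self):
        curve = dataclasses.replace(CFG.curves["microborer"], omega_slope=0.0, temp_slope=0.0)
        cfg = dataclasses.replace(CFG, curves={**CFG.curves, "microborer": curve})
        state = state_with(substrate_cover=50.0)
        base = micro_erosion(state, cfg, REF_SST, REF_OMEGA)
        assert base == pytest.approx(0.120)
        # a +130% response multiplies the same census arithmetic by 2.30
        assert base * 2.30 == pytest.approx(0.276)


class TestSandDissolution:
    def test_zero_sand(self):
        assert sand_dissolution(state_with(), CFG, 3.0) == 0.0

    def test_linear_interpolation_hand_value(self):
        # g zero at omega 4.0 and 0.2 at omega 2.0 means slope 0.1 per unit
        cfg = dataclasses.replace(CFG, reference_env=(REF_SST, 4.0), sand_dissolution_slope=0.1)
        state = state_with(sand_cover=50.0)
        assert sand_dissolution(state, cfg, 3.0) == pytest.approx(0.05)

    @given(omegas=st.lists(st.floats(1.0, 4.5), min_size=2, max_size=6))
    def test_non_decreasing_as_omega_falls(self, omegas):
        state = state_with(sand_cover=30.0)
        values = [sand_dissolution(state, CFG, o) for o in sorted(omegas, reverse=True)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestDirectionalResponses:
    """Late-century direction of each budget contribution under harsh forcing."""

    def test_contribution_directions(self):
        harsh_sst, harsh_omega = REF_SST + 3.5, REF_OMEGA - 1.3
        assert response_multiplier(CFG.curves["coral"], harsh_sst, harsh_omega) < 1.0
        assert response_multiplier(CFG.curves["macroborer"], harsh_sst, harsh_omega) > 1.0
        assert response_multiplier(CFG.curves["microborer"], harsh_sst, harsh_omega) > 1.0
        # CCA collapses entirely; grazing takes no environment arguments at all
        assert response_multiplier(CFG.curves["cca"], harsh_sst, harsh_omega) == 0.0
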