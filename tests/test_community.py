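import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefcast.community import (
    DEFAULT_PHASE_TARGETS,
    DEFAULT_RESTORATION_GROUPS,
    MortalityTable,
    TransectState,
    apply_bleaching_mortality,
    apply_growth,
    apply_restoration,
    build_restoration_schedule,
    derive_modest_loss,
)
from reefcast.errors import ConfigurationError, InvalidParameterError
from reefcast.thermal_stress import Severity

# published severe-bleaching (ASB) and modest-bleaching (MB) loss rates, %
TABLE_LOSSES = {
    "Orbicella faveolata": (6.8, 2.3),
    "Orbicella annularis": (4.5, 1.5),
    "Siderastrea siderea": (1.7, 0.6),
    "Porites astreoides": (11.0, 3.7),
    "Porites porites": (11.0, 3.7),
    "Colpophyllia natans": (7.1, 2.4),
    "Montastraea cavernosa": (12.5, 4.2),
}


class TestDeriveModestLoss:
    @pytest.mark.parametrize("asb,mb", TABLE_LOSSES.values())
    def test_one_third_rule_reproduces_published_rates(self, asb, mb):
        assert derive_modest_loss(asb) == mb

    def test_zero(self):
        assert derive_modest_loss(0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            derive_modest_loss(101.0)


class TestTransectState:
    def test_over_100_percent_rejected(self):
        with pytest.raises(InvalidParameterError):
            TransectState("T", {"X": 60.0}, 20.0, 20.0, 10.0, 1.5)

    def test_rugosity_below_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            TransectState("T", {"X": 10.0}, 1.0, 1.0, 1.0, 0.9)

    def test_nonpositive_urchin_diameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            TransectState("T", {}, 0, 0, 0, 1.0, urchin_sizes={"Echinometra": (0.0,)})


class TestGrowth:
    def test_baseline_one_percent(self, simple_state):
        grown = apply_growth(simple_state, bleaching_year=False)
        assert grown.coral_cover["Orbicella faveolata"] == pytest.approx(25.25)

    def test_bleaching_year_half_percent(self, simple_state):
        state = dataclasses.replace(simple_state, coral_cover={"Orbicella faveolata": 20.0})
        grown = apply_growth(state, bleaching_year=True)
        assert grown.coral_cover["Orbicella faveolata"] == pytest.approx(20.10)

    def test_zero_cover_stays_zero(self, simple_state):
        state = dataclasses.replace(simple_state, coral_cover={"Orbicella faveolata": 0.0})
        assert apply_growth(state, False).coral_cover["Orbicella faveolata"] == 0.0

    def test_clamped_at_full_benthos(self):
        state = TransectState("T", {"X": 50.0}, 0.0, 25.0, 25.0, 1.0)
        grown = apply_growth(state, False)
        assert grown.total_cover == pytest.approx(100.0)
        assert grown.coral_cover["X"] == pytest.approx(50.0)


class TestMortality:
    def test_severe_loss_on_dominant_species(self, simple_state):
        state = dataclasses.replace(simple_state, coral_cover={"Orbicella faveolata": 10.0})
        hit = apply_bleaching_mortality(state, Severity.SEVERE, MortalityTable.default())
        assert hit.coral_cover["Orbicella faveolata"] == pytest.approx(9.32)

    def test_none_is_identity(self, simple_state):
        out = apply_bleaching_mortality(simple_state, Severity.NONE, MortalityTable.default())
        assert out is simple_state

    def test_modest_loss_hand_value(self, simple_state):
        state = dataclasses.replace(simple_state, coral_cover={"Montastraea cavernosa": 8.0})
        hit = apply_bleaching_mortality(state, Severity.MODEST, MortalityTable.default())
        assert hit.coral_cover["Montastraea cavernosa"] == pytest.approx(8 * (1 - 0.042))

    def test_lost_cover_becomes_substrate(self, simple_state):
        state = dataclasses.replace(simple_state, coral_cover={"Orbicella faveolata": 10.0})
        hit = apply_bleaching_mortality(state, Severity.SEVERE, MortalityTable.default())
        assert hit.substrate_cover == pytest.approx(state.substrate_cover + 10 * 0.068)
        assert hit.total_cover == pytest.approx(state.total_cover)

    def test_cover_never_reaches_zero(self, simple_state):
        state = dataclasses.replace(simple_state, coral_cover={"Orbicella faveolata": 1.0})
        for _ in range(200):
            state = apply_bleaching_mortality(state, Severity.SEVERE, MortalityTable.default())
        assert 0.0 < state.coral_cover["Orbicella faveolata"] < 1e-3

    def test_missing_taxon_uses_cover_weighted_fallback(self, simple_state):
        state = dataclasses.replace(
            simple_state,
            coral_cover={"Orbicella faveolata": 10.0, "Unknownia species": 5.0},
        )
        hit = apply_bleaching_mortality(state, Severity.SEVERE, MortalityTable.default())
        # only tabulated cover is O. faveolata, so fallback = its loss rate
        assert hit.coral_cover["Unknownia species"] == pytest.approx(5 * (1 - 0.068))

    def test_missing_taxon_without_fallback_rejected(self, simple_state):
        table = dataclasses.replace(MortalityTable.default(), fallback=None)
        state = dataclasses.replace(simple_state, coral_cover={"Unknownia species": 5.0})
        with pytest.raises(ConfigurationError):
            apply_bleaching_mortality(state, Severity.SEVERE, table)


class TestRestorationSchedule:
    def test_phase_one_orbicella_annual_addition(self):
        sched = build_restoration_schedule()
        for year in range(2022, 2032):
            assert sched.additions[year]["Orbicella"] == pytest.approx(1.65 / 10)

    def test_phase_totals_match_published_targets(self):
        sched = build_restoration_schedule()
        phase1 = sum(
            sched.additions[y][g] for y in range(2022, 2032) for g in sched.additions[y]
        )
        phase2 = sum(
            sched.additions[y][g] for y in range(2032, 2042) for g in sched.additions[y]
        )
        assert phase1 == pytest.approx(2.80)
        assert phase2 == pytest.approx(6.20)
        assert sched.total_added() == pytest.approx(9.0)

    def test_zero_targets_give_empty_schedule(self):
        sched = build_restoration_schedule({1: {"Orbicella": 0.0}}, {1: 2022})
        assert sched.additions == {}

    def test_negative_target_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_restoration_schedule({1: {"Orbicella": -1.0}}, {1: 2022})


class TestApplyRestoration:
    def test_year_outside_schedule_unchanged(self, simple_state):
        sched = build_restoration_schedule()
        assert apply_restoration(simple_state, 2019, sched) is simple_state

    def test_brain_group_split_evenly(self, simple_state):
        sched = build_restoration_schedule({1: {"Brain": 1.15}}, {1: 2022})
        out = apply_restoration(simple_state, 2022, sched)
        assert out.coral_cover["Diploria labyrinthiformis"] == pytest.approx(0.0575)
        assert out.coral_cover["Colpophyllia natans"] == pytest.approx(0.0575)

    def test_ten_years_accumulate_phase_target(self, simple_state):
        sched = build_restoration_schedule({1: {"Orbicella": 1.65}}, {1: 2022})
        state = dataclasses.replace(simple_state, coral_cover={})
        for year in range(2022, 2032):
            state = apply_restoration(state, year, sched)
        assert state.total_coral_cover == pytest.approx(1.65)

    def test_draws_substrate_before_sand(self, simple_state):
        sched = build_restoration_schedule({1: {"Orbicella": 5.0}}, {1: 2022}, 1)
        out = apply_restoration(simple_state, 2022, sched)
        assert out.substrate_cover == pytest.approx(simple_state.substrate_cover - 5.0)
        assert out.sand_cover == pytest.approx(simple_state.sand_cover)
        assert out.total_cover == pytest.approx(simple_state.total_cover)

    def test_truncated_when_benthos_full(self, caplog):
        state = TransectState("T", {"Orbicella faveolata": 95.0}, 0.0, 1.0, 2.0, 1.0)
        sched = build_restoration_schedule({1: {"Orbicella": 10.0}}, {1: 2022}, 1)
        with caplog.at_level("WARNING"):
            out = apply_restoration(state, 2022, sched)
        assert out.total_cover <= 100 + 1e-9
        assert out.substrate_cover == pytest.approx(0.0)
        assert out.sand_cover == pytest.approx(0.0)
        assert any("truncated" in r.message for r in caplog.records)

    @given(pp=st.floats(0.0, 3.0))
    def test_invariants_preserved(self, simple_state, pp):
        sched = build_restoration_schedule({1: {"Orbicella": pp}}, {1: 2022}, 1)
        out = apply_restoration(simple_state, 2022, sched)
        assert out.total_cover <= 100 + 1e-9
        assert out.total_coral_cover >= simple_state.total_coral_cover
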