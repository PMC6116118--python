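"""BQI scoring, energy-density partition and skipping classification."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bqikit.breakfast_metrics import (
    BQI_ITEMS,
    classify_skipping,
    compute_energy_density,
    score_bqi,
    summarize_participant,
)
from bqikit.errors import DomainError
from bqikit.recall_io import BreakfastRecord, RecallLine, ResolvedFood, resolve_day

from conftest import BQI_PANEL


def _tagged_food(groups, *, grams=10.0, energy=0.0, mufa=0.0, sfa=0.0, calcium=0.0,
                 is_beverage=False, is_energy_beverage=False):
    """A minimal resolved food carrying only tags (and optional nutrients)."""
    fat = mufa + sfa
    return ResolvedFood(
        food_id="synthetic",
        grams=grams,
        energy_kcal=energy,
        carb_g=0.0,
        simple_sugar_g=0.0,
        fat_g=fat,
        mufa_g=mufa,
        sfa_g=sfa,
        protein_g=0.0,
        calcium_mg=calcium,
        groups=frozenset(groups),
        is_beverage=is_beverage,
        is_energy_beverage=is_energy_beverage,
    )


class TestScoreBqi:
    @pytest.mark.parametrize("label, foods, daily, expected", BQI_PANEL,
                             ids=[p[0] for p in BQI_PANEL])
    def test_hand_scored_panel_matches_item_by_item(
        self, make_breakfast, label, foods, daily, expected
    ):
        result = score_bqi(make_breakfast(foods), daily)
        assert {k for k, v in result.items.items() if v} == expected
        assert result.score == len(expected)

    def test_empty_breakfast_scores_zero(self):
        result = score_bqi(None, 1800.0)
        assert result.score == 0
        assert not any(result.items.values())

    def test_nonpositive_daily_energy_is_domain_error(self, make_breakfast):
        with pytest.raises(DomainError):
            score_bqi(make_breakfast([("apple", 100)]), 0.0)

    def test_zero_sfa_with_positive_mufa_meets_ratio(self):
        bf = BreakfastRecord([_tagged_food({"other"}, mufa=1.0, sfa=0.0)])
        assert score_bqi(bf, 1000.0).items["mufa_sfa_ratio"]
        bf0 = BreakfastRecord([_tagged_food({"other"}, mufa=0.0, sfa=0.0)])
        assert not score_bqi(bf0, 1000.0).items["mufa_sfa_ratio"]

    @pytest.mark.parametrize("share, expected", [(0.199, False), (0.20, True),
                                                 (0.25, True), (0.251, False)])
    def test_energy_share_band_inclusive(self, share, expected):
        bf = BreakfastRecord([_tagged_food({"other"}, energy=share * 1000.0)])
        assert score_bqi(bf, 1000.0).items["energy_share"] is expected

    def test_calcium_lower_bound_and_configurability(self):
        bf = BreakfastRecord([_tagged_food({"other"}, calcium=200.0)])
        assert score_bqi(bf, 1000.0).items["calcium"]
        assert not score_bqi(bf, 1000.0, calcium_min_mg=300.0).items["calcium"]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_score_bounded_and_combined_item_implies_components(self, data):
        foods = data.draw(
            st.lists(
                st.builds(
                    lambda groups, grams, energy, fat, u, v, ca, bev: ResolvedFood(
                        food_id="f",
                        grams=grams,
                        energy_kcal=energy,
                        carb_g=0.0,
                        simple_sugar_g=0.0,
                        fat_g=fat,
                        mufa_g=fat * u * v,
                        sfa_g=fat * u * (1 - v),
                        protein_g=0.0,
                        calcium_mg=ca,
                        groups=frozenset(groups),
                        is_beverage=bev,
                        is_energy_beverage=bev and energy > 0,
                    ),
                    groups=st.sets(
                        st.sampled_from(
                            ["cereal", "fruit_or_vegetable", "dairy", "olive_oil",
                             "butter_margarine", "sugar_rich", "other"]
                        ),
                        min_size=1,
                        max_size=3,
                    ),
                    grams=st.floats(1.0, 500.0),
                    energy=st.floats(0.0, 800.0),
                    fat=st.floats(0.0, 50.0),
                    u=st.floats(0.0, 1.0),
                    v=st.floats(0.0, 1.0),
                    ca=st.floats(0.0, 500.0),
                    bev=st.booleans(),
                ),
                min_size=0,
                max_size=6,
            )
        )
        daily = data.draw(st.floats(500.0, 3500.0))
        result = score_bqi(BreakfastRecord(foods) if foods else None, daily)
        assert 0 <= result.score <= 10
        if result.items["cereal_fruit_dairy"]:
            assert result.items["cereal"] and result.items["fruit_vegetable"]
            assert result.items["dairy"]

    def test_adding_butter_tag_never_raises_score(self, make_breakfast):
        for _, foods, daily, _expected in BQI_PANEL:
            base = make_breakfast(foods)
            spiked = BreakfastRecord(list(base.foods) + [_tagged_food({"butter_margarine"})])
            assert score_bqi(spiked, daily).score <= score_bqi(base, daily).score

    def test_adding_dairy_tag_never_lowers_score(self, make_breakfast):
        for _, foods, daily, _expected in BQI_PANEL:
            base = make_breakfast(foods)
            spiked = BreakfastRecord(list(base.foods) + [_tagged_food({"dairy"})])
            assert score_bqi(spiked, daily).score >= score_bqi(base, daily).score


class TestEnergyDensity:
    def test_solids_only(self):
        bf = BreakfastRecord([_tagged_food({"other"}, grams=80.0, energy=264.0)])
        result = compute_energy_density(bf)
        assert result.beds_kcal_per_g == pytest.approx(3.3)
        assert result.bedb_kcal_per_g is None

    def test_water_excluded_from_beverage_denominator(self):
        milk = _tagged_food({"dairy"}, grams=250.0, energy=125.0,
                            is_beverage=True, is_energy_beverage=True)
        water = _tagged_food({"other"}, grams=100.0, energy=0.0,
                             is_beverage=True, is_energy_beverage=False)
        result = compute_energy_density(BreakfastRecord([milk, water]))
        assert result.bedb_kcal_per_g == pytest.approx(0.5)
        assert result.beds_kcal_per_g is None

    def test_line_splitting_leaves_beds_unchanged(self, demo_library):
        combined = resolve_day(
            [RecallLine("P1", 1, "breakfast", "white_bread", 60.0),
             RecallLine("P1", 1, "breakfast", "olive_oil", 10.0)],
            demo_library,
        )
        split = resolve_day(
            [RecallLine("P1", 1, "breakfast", "white_bread", 30.0),
             RecallLine("P1", 1, "breakfast", "white_bread", 30.0),
             RecallLine("P1", 1, "breakfast", "olive_oil", 10.0)],
            demo_library,
        )
        assert compute_energy_density(split.breakfast).beds_kcal_per_g == pytest.approx(
            compute_energy_density(combined.breakfast).beds_kcal_per_g
        )

    def test_adding_any_beverage_leaves_beds_unchanged(self):
        solid = _tagged_food({"other"}, grams=100.0, energy=250.0)
        base = compute_energy_density(BreakfastRecord([solid]))
        for bev_energy in (0.0, 90.0):
            spiked = BreakfastRecord(
                [solid, _tagged_food({"other"}, grams=200.0, energy=bev_energy,
                                     is_beverage=True, is_energy_beverage=bev_energy > 0)]
            )
            assert compute_energy_density(spiked).beds_kcal_per_g == pytest.approx(
                base.beds_kcal_per_g
            )

    def test_adding_solid_or_water_leaves_bedb_unchanged(self):
        milk = _tagged_food({"dairy"}, grams=200.0, energy=120.0,
                            is_beverage=True, is_energy_beverage=True)
        base = compute_energy_density(BreakfastRecord([milk])).bedb_kcal_per_g
        with_solid = BreakfastRecord([milk, _tagged_food({"other"}, grams=50.0, energy=200.0)])
        with_water = BreakfastRecord(
            [milk, _tagged_food({"other"}, grams=150.0, is_beverage=True)]
        )
        assert compute_energy_density(with_solid).bedb_kcal_per_g == pytest.approx(base)
        assert compute_energy_density(with_water).bedb_kcal_per_g == pytest.approx(base)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k=st.floats(0.1, 10.0))
    def test_scaling_all_masses_leaves_densities_unchanged(self, make_breakfast, k):
        foods = [("white_bread", 60.0), ("semi_milk", 200.0), ("olive_oil", 10.0)]
        base = compute_energy_density(make_breakfast(foods))
        scaled = compute_energy_density(
            make_breakfast([(fid, g * k) for fid, g in foods])
        )
        assert scaled.beds_kcal_per_g == pytest.approx(base.beds_kcal_per_g)
        assert scaled.bedb_kcal_per_g == pytest.approx(base.bedb_kcal_per_g)


class TestSkipping:
    def _day(self, demo_library, idx, with_breakfast):
        lines = [RecallLine("P1", idx, "lunch", "lunch_mixed", 300.0)]
        if with_breakfast:
            lines.append(RecallLine("P1", idx, "breakfast", "semi_milk", 200.0))
        return resolve_day(lines, demo_library)

    def test_skipper_requires_absence_on_both_days(self, demo_library):
        none1 = self._day(demo_library, 1, False)
        none2 = self._day(demo_library, 2, False)
        one = self._day(demo_library, 1, True)
        assert classify_skipping(none1, none2).by_recall
        assert not classify_skipping(one, none2).by_recall

    def test_kidmed_echoed_and_unknown_propagates(self, demo_library):
        d1 = self._day(demo_library, 1, True)
        d2 = self._day(demo_library, 2, True)
        assert classify_skipping(d1, d2, True).by_kidmed is True
        status = classify_skipping(d1, d2, None)
        assert status.by_kidmed is None
        assert status.by_recall is False


class TestSummarizeParticipant:
    def test_per_day_scores_are_averaged(self, demo_library):
        perfect = [
            RecallLine("P1", 1, "breakfast", "wholegrain_bread", 50.0),
            RecallLine("P1", 1, "breakfast", "apple", 100.0),
            RecallLine("P1", 1, "breakfast", "semi_milk", 200.0),
            RecallLine("P1", 1, "breakfast", "olive_oil", 12.0),
            RecallLine("P1", 1, "lunch", "lunch_mixed", 680.2344),  # daily = 1600
        ]
        milk_only = [
            RecallLine("P1", 2, "breakfast", "semi_milk", 250.0),
            RecallLine("P1", 2, "lunch", "lunch_mixed", 823.6111),  # daily = 1600
        ]
        d1 = resolve_day(perfect, demo_library)
        d2 = resolve_day(milk_only, demo_library)
        row = summarize_participant(d1, d2)
        assert row["bqi_score"] == pytest.approx((10 + 4) / 2)
        assert row["breakfast_days"] == 2
        assert row["item_dairy"] == 1.0  # met both days
        assert row["item_cereal"] == 0.5  # met on day 1 only

    def test_no_breakfast_either_day_scores_zero(self, demo_library):
        d1 = resolve_day([RecallLine("P1", 1, "lunch", "lunch_mixed", 300.0)], demo_library)
        d2 = resolve_day([RecallLine("P1", 2, "lunch", "lunch_mixed", 300.0)], demo_library)
        row = summarize_participant(d1, d2)
        assert row["bqi_score"] == 0.0
        assert row["beds"] is None and row["bedb"] is None
        assert row["skip_recall"] is True
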