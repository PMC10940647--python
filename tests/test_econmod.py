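import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from weedrot import density_model as dm
from weedrot import econmod as em
from weedrot.strategies import ManagementYear

NO_WEEDS = np.array([1.0, 0, 0, 0, 0])


@pytest.fixture()
def toy_penalties():
    return em.YieldPenaltyTable(
        lower=[0, 0, 0, 0.1, 0.2],
        central=[0, 0, 0, 0.2, 0.4],
        upper=[0, 0, 0, 0.3, 0.6],
    )


class TestWheatYield:
    def test_no_weeds_full_yield(self, toy_penalties):
        assert em.wheat_yield(8.0, NO_WEEDS, toy_penalties) == pytest.approx(8.0)

    def test_hand_weighted_sum(self, toy_penalties, toy_distribution):
        # losses (0,0,0,0.2,0.4) on (0.1,0.1,0.2,0.3,0.3): 8 * 0.82 = 6.56
        assert em.wheat_yield(8.0, toy_distribution, toy_penalties) == pytest.approx(6.56)

    def test_medium_state_zero_penalty(self, toy_penalties):
        assert em.wheat_yield(8.0, [0, 0, 1, 0, 0], toy_penalties) == pytest.approx(8.0)

    def test_invalid_distribution_errors(self, toy_penalties):
        with pytest.raises(ValueError):
            em.wheat_yield(8.0, [0.5, 0.5, 0.5, 0, 0], toy_penalties)

    def test_sensitivity_bound_selection(self, toy_penalties, toy_distribution):
        lower = em.wheat_yield(8.0, toy_distribution, toy_penalties, "lower")
        central = em.wheat_yield(8.0, toy_distribution, toy_penalties, "central")
        upper = em.wheat_yield(8.0, toy_distribution, toy_penalties, "upper")
        assert lower >= central >= upper


class TestPenaltyTableInvariants:
    def test_nonzero_low_state_penalty_rejected(self):
        with pytest.raises(ValueError, match="zero penalty"):
            em.YieldPenaltyTable(
                lower=[0, 0.1, 0, 0.1, 0.2],
                central=[0, 0.1, 0, 0.2, 0.4],
                upper=[0, 0.1, 0, 0.3, 0.6],
            )

    def test_bounds_ordering_enforced(self):
        with pytest.raises(ValueError, match="lower <= central"):
            em.YieldPenaltyTable(
                lower=[0, 0, 0, 0.3, 0.5],
                central=[0, 0, 0, 0.2, 0.4],
                upper=[0, 0, 0, 0.3, 0.6],
            )


class TestYearCosts:
    def test_fallow_zero_herbicide(self, prices):
        year = ManagementYear("fallow", "none", "min_till")
        costs = em.year_costs(year, prices)
        assert costs["herbicide"] == 0.0

    def test_glyphosate_linearity(self, prices):
        y1 = ManagementYear(
            "winter_wheat", "late_autumn", "min_till",
            glyphosate_applications=1, glyphosate_dose=2.0,
        )
        y2 = ManagementYear(
            "winter_wheat", "late_autumn", "min_till",
            glyphosate_applications=1, glyphosate_dose=4.0,
        )
        c1 = em.year_costs(y1, prices)
        c2 = em.year_costs(y2, prices)
        glyph1 = c1["herbicide"]
        assert c2["herbicide"] == pytest.approx(2 * glyph1)

    def test_mit_hdhr_wheat_year_glyphosate_geq_bau(self, prices, bau, mit_strategies):
        bau_wheat = next(y for y in bau.years if y.crop == "winter_wheat")
        mit = next(
            s for s in mit_strategies
            if s.dr_category == "HD-HR" and s.soil == "medium" and s.region == "central"
        )
        mit_wheat = next(y for y in mit.years if y.crop == "winter_wheat")
        bau_glyph = bau_wheat.glyphosate_dose * prices.glyphosate_cost
        mit_glyph = mit_wheat.glyphosate_dose * prices.glyphosate_cost
        assert mit_glyph >= bau_glyph


class TestGrossProfitYear:
    def test_accounting_identity_toy(self):
        year = em.EconYear(
            crop="winter_wheat", output=1000.0, potential_output=1100.0,
            herbicide_cost=300.0, operations_cost=150.0, other_cost=250.0,
            wheat_yield=6.0,
        )
        assert year.gross_profit == pytest.approx(300.0)

    def test_zero_weed_field_no_income_gap(
        self, prices, base_yields, penalties, bau
    ):
        res = em.gross_profit_year(
            bau.years[0], NO_WEEDS, prices, base_yields, penalties, "medium", "central"
        )
        assert res.output == pytest.approx(res.potential_output)

    def test_hand_computed_toy_year(self, toy_penalties, toy_distribution):
        prices = em.PriceTable(
            crop_price={c: 150.0 for c in em.CROPS},
            glyphosate_cost=0.0,
            selective_cost=0.0,
            operation_costs={op: 0.0 for op in em.OPERATION_TYPES},
            other_costs={c: 0.0 for c in em.CROPS},
        )
        base = em.BaseYieldTable(
            yields={("winter_wheat", "medium", "central"): 8.0}
        )
        year = ManagementYear("winter_wheat", "late_autumn", "min_till")
        res = em.gross_profit_year(
            year, toy_distribution, prices, base, toy_penalties, "medium", "central"
        )
        # yield 6.56 t/ha at 150 GBP/t, costs only the fitted zeros + other
        assert res.output == pytest.approx(984.0)
        assert res.gross_profit == pytest.approx(984.0 - res.total_cost)
        assert res.total_cost == pytest.approx(
            em.year_costs(year, prices)["operations"]
            + em.year_costs(year, prices)["herbicide"]
            + em.year_costs(year, prices)["other"]
        )

    def test_unpriced_crop_errors(self, base_yields, penalties):
        prices = em.PriceTable(
            crop_price={c: 10.0 for c in em.CROPS},
            glyphosate_cost=1.0,
            selective_cost=1.0,
            operation_costs={op: 1.0 for op in em.OPERATION_TYPES},
            other_costs={c: 1.0 for c in em.CROPS},
        )
        del prices.other_costs["fallow"]
        year = ManagementYear("fallow", "none", "min_till")
        with pytest.raises(KeyError, match="fallow"):
            em.year_costs(year, prices)

    @settings(max_examples=40, deadline=None)
    @given(
        glyph=hs.floats(min_value=0, max_value=20, allow_nan=False),
        selective=hs.floats(min_value=0, max_value=20, allow_nan=False),
    )
    def test_accounting_identity_property(
        self, glyph, selective, prices, base_yields, penalties, toy_distribution
    ):
        year = ManagementYear(
            "winter_wheat", "late_autumn", "min_till",
            glyphosate_applications=1, glyphosate_dose=glyph,
            selective_applications=1, selective_dose=selective,
        )
        res = em.gross_profit_year(
            year, toy_distribution, prices, base_yields, penalties, "heavy", "north"
        )
        assert res.gross_profit == res.output - (
            res.herbicide_cost + res.operations_cost + res.other_cost
        )


class TestMonotonicity:
    def test_more_damaging_mass_never_raises_profit(
        self, prices, base_yields, penalties, bau
    ):
        mild = np.array([0.4, 0.3, 0.2, 0.05, 0.05])
        worse = np.array([0.3, 0.3, 0.2, 0.1, 0.1])
        year = bau.years[0]
        res_mild = em.gross_profit_year(
            year, mild, prices, base_yields, penalties, "medium", "central"
        )
        res_worse = em.gross_profit_year(
            year, worse, prices, base_yields, penalties, "medium", "central"
        )
        assert res_worse.wheat_yield <= res_mild.wheat_yield
        assert res_worse.output <= res_mild.output
        assert res_worse.gross_profit <= res_mild.gross_profit


class TestRotationSummary:
    def _constant_year(self, profit):
        return em.EconYear(
            crop="winter_wheat", output=profit, potential_output=profit,
            herbicide_cost=0.0, operations_cost=0.0, other_cost=0.0,
            wheat_yield=0.0,
        )

    def test_constant_profit_mean(self):
        per_year = [[self._constant_year(600.0) for _ in range(6)]]
        summary = em.rotation_summary(per_year)
        assert summary.mean_gross_profit == pytest.approx(600.0)

    def test_wheat_yield_total_over_rotation_length(self):
        years = [
            em.EconYear("winter_wheat", 0, 0, 0, 0, 0, wheat_yield=1.15)
            for _ in range(4)
        ] + [em.EconYear("fallow", 0, 0, 0, 0, 0, wheat_yield=0.0)] * 2
        summary = em.rotation_summary([years])
        assert summary.mean_wheat_yield == pytest.approx(4 * 1.15 / 6)

    def test_identical_imputations_zero_width_envelope(self):
        per_year = [[self._constant_year(500.0)] * 6] * 3
        summary = em.rotation_summary(per_year)
        assert summary.gross_profit_range == (500.0, 500.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            em.rotation_summary([])


class TestEvaluateRotation:
    def test_sensitivity_ordering_over_rotation(
        self, prices, base_yields, penalties, bau, effective_model
    ):
        traj = dm.simulate_density(
            effective_model, bau, dm.WORST_CASE_DISTRIBUTION, "high"
        )
        profits = {
            bound: em.evaluate_rotation(
                bau.years, traj, prices, base_yields, penalties,
                "medium", "central", bound=bound,
            ).mean_gross_profit
            for bound in ("lower", "central", "upper")
        }
        assert profits["upper"] <= profits["central"] <= profits["lower"]

    def test_length_mismatch_errors(
        self, prices, base_yields, penalties, bau, effective_model
    ):
        traj = dm.simulate_density(
            effective_model, bau, dm.WORST_CASE_DISTRIBUTION, "high"
        )
        with pytest.raises(ValueError, match="plan has"):
            em.evaluate_rotation(
                bau.years[:3], traj, prices, base_yields, penalties, "medium", "central"
            )


class TestRefineAndAverage:
    def test_identical_values(self):
        assert em.refine_and_average([700.0, 700.0]) == 700.0

    def test_two_subcategories(self):
        assert em.refine_and_average({"a": 600.0, "b": 700.0}) == 650.0

    @given(hs.lists(hs.floats(-1e5, 1e5), min_size=1, max_size=12))
    def test_matches_brute_force_mean(self, values):
        assert em.refine_and_average(values) == pytest.approx(
            sum(values) / len(values), rel=1e-12, abs=1e-9
        )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            em.refine_and_average([])
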