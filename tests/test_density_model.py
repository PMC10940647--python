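import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs
from scipy.special import expit

from weedrot import density_model as dm
from weedrot import synthetic_data as sd
from weedrot.strategies import ManagementYear

ZERO_MODEL_ROW = np.diff(
    np.concatenate([[0.0], expit(np.array([-2.0, -1.0, 1.0, 2.0])), [1.0]])
)


def _wheat_year(**kw):
    base = dict(
        crop="winter_wheat",
        sowing_window="late_autumn",
        tillage="min_till",
        n_stale_seedbeds=1,
        glyphosate_applications=1,
        glyphosate_dose=1.5,
        selective_applications=2,
        selective_dose=2.0,
    )
    base.update(kw)
    return ManagementYear(**base)


class TestDistributionHelpers:
    def test_prop_damaging_worst_case(self, toy_distribution):
        assert dm.prop_damaging(toy_distribution) == pytest.approx(0.6)

    def test_prop_damaging_no_weeds(self):
        assert dm.prop_damaging([1, 0, 0, 0, 0]) == 0.0

    def test_prop_damaging_all_damaging(self):
        assert dm.prop_damaging([0, 0, 0, 0.5, 0.5]) == 1.0

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            dm.check_distribution([0.5, 0.5, 0.5, 0, 0])


class TestEncodeCovariates:
    def test_bau_year3_transition(self, bau):
        cov = dm.encode_covariates(bau.years[2], bau.years[1].crop, 0, "high")
        assert cov.crop_transition == "winter_wheat->winter_oilseed_rape"

    def test_unseen_transition_flagged_missing(self, bau):
        cov = dm.encode_covariates(
            bau.years[0], "spring_beans", 0, "high", vocab=("a->b",)
        )
        assert cov.missing_transition

    def test_identical_inputs_identical_encoding(self, bau):
        a = dm.encode_covariates(bau.years[0], "winter_oilseed_rape", 2, "low")
        b = dm.encode_covariates(bau.years[0], "winter_oilseed_rape", 2, "low")
        assert a == b

    def test_unregistered_crop_errors(self, bau):
        with pytest.raises(ValueError, match="maize"):
            dm.encode_covariates(bau.years[0], "maize", 0, "low")

    def test_proxy_map_applied(self, bau):
        cov = dm.encode_covariates(
            bau.years[2],
            "winter_wheat",
            0,
            "high",
            proxy_map={"winter_oilseed_rape": "spring_barley"},
        )
        assert cov.crop_transition == "winter_wheat->spring_barley"


class TestTransitionMatrix:
    def test_zero_coefficients_rows(self, zero_model, bau):
        cov = dm.encode_covariates(
            ManagementYear("winter_wheat", "early_autumn", "inversion_plough"),
            "winter_wheat",
            0,
            "low",
        )
        M = dm.transition_matrix(zero_model, cov, 0)
        for row in M:
            np.testing.assert_allclose(row, ZERO_MODEL_ROW, atol=1e-9)
        np.testing.assert_allclose(
            ZERO_MODEL_ROW, [0.1192, 0.1497, 0.4621, 0.1497, 0.1192], atol=5e-5
        )

    def test_large_positive_effect_concentrates_on_very_high(self):
        model = dm.make_known_model(
            cutpoints=(-2, -1, 1, 2), beta={"resistance:high": 50.0}
        )
        cov = dm.encode_covariates(
            ManagementYear("winter_wheat", "early_autumn", "inversion_plough"),
            "winter_wheat",
            0,
            "high",
        )
        M = dm.transition_matrix(model, cov, 0)
        assert M[0, 4] > 1 - 1e-9

    @settings(max_examples=50, deadline=None)
    @given(
        coeffs=hs.lists(
            hs.floats(min_value=-3, max_value=3, allow_nan=False),
            min_size=3,
            max_size=3,
        )
    )
    def test_rows_sum_to_one_for_random_coefficients(self, coeffs):
        model = dm.make_known_model(
            cutpoints=(-1.5, -0.5, 0.5, 1.5),
            beta={
                "n_stale_seedbeds": coeffs[0],
                "resistance:high": coeffs[1],
                "prev_state:high": coeffs[2],
            },
        )
        cov = dm.encode_covariates(_wheat_year(), "winter_wheat", 0, "high")
        M = dm.transition_matrix(model, cov, 0)
        np.testing.assert_allclose(M.sum(axis=1), np.ones(5), atol=1e-12)

    def test_monotone_response_stochastic_dominance(self):
        """Raising eta shifts mass to higher states (FOSD)."""
        lo = dm.make_known_model(cutpoints=(-2, -1, 1, 2))
        hi = dm.make_known_model(cutpoints=(-2, -1, 1, 2), beta={"resistance:high": 1.0})
        cov = dm.encode_covariates(_wheat_year(), "winter_wheat", 0, "high")
        M_lo = dm.transition_matrix(lo, cov, 0)
        M_hi = dm.transition_matrix(hi, cov, 0)
        for s in range(5):
            assert np.all(np.cumsum(M_hi[s]) <= np.cumsum(M_lo[s]) + 1e-12)


class TestSimulateDensity:
    def test_identity_model_constant_trajectory(self, toy_distribution, bau):
        traj = dm.simulate_density(
            dm.identity_like_model(), bau, toy_distribution, "high"
        )
        for year in traj.per_imputation[0]:
            np.testing.assert_allclose(year, toy_distribution, atol=1e-12)

    def test_probability_conservation_worst_case(self, effective_model, bau):
        traj = dm.simulate_density(
            effective_model, bau, dm.WORST_CASE_DISTRIBUTION, "high"
        )
        sums = traj.per_imputation.sum(axis=2)
        np.testing.assert_allclose(sums, np.ones_like(sums), atol=1e-9)

    def test_trajectory_length_includes_year_zero(self, effective_model, bau):
        traj = dm.simulate_density(
            effective_model, bau, dm.WORST_CASE_DISTRIBUTION, "high"
        )
        assert traj.per_imputation.shape[1] == 7
        assert traj.n_years == 6

    def test_matrix_chain_oracle(self, effective_model, toy_distribution):
        """2-year toy plan equals hand-multiplied matrix chain."""
        years = (_wheat_year(), _wheat_year(crop="spring_barley", sowing_window="spring"))
        traj = dm.simulate_density(
            effective_model, years, toy_distribution, "high",
            initial_prev_crop="winter_oilseed_rape",
        )
        prev_crops = ["winter_oilseed_rape", "winter_wheat"]
        p = np.asarray(toy_distribution, float)
        expected = [p]
        for year, prev in zip(years, prev_crops):
            cov = dm.encode_covariates(year, prev, 0, "high")
            M = dm.transition_matrix(effective_model, cov, 0)
            p = p @ M
            expected.append(p)
        np.testing.assert_allclose(
            traj.per_imputation[0], np.array(expected), atol=1e-12
        )

    def test_envelope_brackets_every_imputation(self, bau):
        model = sd.default_true_model(n_imputations=4, seed=1)
        # introduce between-imputation spread via an unseen transition draw
        for imp in model.imputations:
            imp.sigma["crop_transition"] = 0.5
        traj = dm.simulate_density(model, bau, dm.WORST_CASE_DISTRIBUTION, "high")
        assert np.all(traj.lower <= traj.per_imputation + 1e-12)
        assert np.all(traj.per_imputation <= traj.upper + 1e-12)
        mean = traj.mean
        np.testing.assert_allclose(mean.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_plan_errors(self, effective_model, toy_distribution):
        with pytest.raises(ValueError, match="empty"):
            dm.simulate_density(effective_model, (), toy_distribution, "high")


@pytest.fixture(scope="module")
def fitted():
    true = sd.default_true_model()
    hist = sd.gen_covariate_rich_histories(30, 4, seed=21)
    records = sd.gen_transition_dataset(true, hist, seed=21, n_quadrats=25)
    model = dm.fit_transition_model(records, n_imputations=3, seed=21)
    return records, model


class TestFitTransitionModel:
    def test_cutpoints_increasing_every_imputation(self, fitted):
        _, model = fitted
        for imp in model.imputations:
            assert np.all(np.diff(imp.cutpoints) > 0)

    def test_diagnostics_exposed(self, fitted):
        _, model = fitted
        assert model.diagnostics["converged"]
        assert model.diagnostics["n_records"] > 0
        assert set(model.diagnostics["sigmas"]) == set(dm.RANDOM_EFFECT_GROUPS)

    def test_complete_data_imputations_agree(self, fitted, toy_distribution, bau):
        _, model = fitted
        traj = dm.simulate_density(model, bau, toy_distribution, "high")
        across_sd = traj.per_imputation.std(axis=0)
        assert np.all(across_sd < 1e-12)  # identical coefficient sets

    def test_unseen_transition_draws_differ_across_imputations(self, fitted):
        _, model = fitted
        effects = [
            model._transition_effect("cover_crop->winter_wheat", i)
            for i in range(model.n_imputations)
        ]
        assert len(set(effects)) == model.n_imputations
        assert ("cover_crop->winter_wheat" in dict(model.imputed_transitions).values()
                or model.imputed_transitions)

    def test_unseen_transition_draw_is_stable(self, fitted):
        _, model = fitted
        first = model._transition_effect("fallow->winter_wheat", 0)
        again = model._transition_effect("fallow->winter_wheat", 0)
        assert first == again

    def test_degenerate_single_state_errors(self):
        records = pd.DataFrame(
            {
                "prev_state": [2] * 10,
                "next_state": [2] * 10,
                "crop_transition": ["a->b"] * 10,
                "sowing_window": ["spring"] * 10,
                "tillage": ["min_till"] * 10,
                "n_stale_seedbeds": [0] * 10,
                "glyphosate_applications": [0] * 10,
                "selective_applications": [0] * 10,
                "seed_rate": [1.0] * 10,
                "resistance": ["high"] * 10,
                "field_id": ["f"] * 10,
                "rotation_id": ["r"] * 10,
            }
        )
        with pytest.raises(dm.ModelFitError, match="degenerate"):
            dm.fit_transition_model(records, n_imputations=1, seed=0)

    def test_missing_columns_errors(self):
        with pytest.raises(ValueError, match="missing columns"):
            dm.fit_transition_model(pd.DataFrame({"prev_state": [0]}))

    def test_json_round_trip_preserves_predictions(self, fitted, tmp_path, bau):
        _, model = fitted
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = dm.TransitionModel.from_json(path)
        cov = dm.encode_covariates(bau.years[0], "winter_oilseed_rape", 0, "high")
        np.testing.assert_allclose(
            dm.transition_matrix(model, cov, 0),
            dm.transition_matrix(loaded, cov, 0),
            atol=1e-12,
        )
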