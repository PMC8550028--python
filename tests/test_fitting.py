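import numpy as np
import pytest

from visconf.data_model import EXP1_DESIGN, CountTable, ExperimentDesign, tabulate
from visconf.fitting import (
    FitSettings,
    aicc,
    bic,
    fit_model,
    negative_log_likelihood,
    pack_parameters,
    unpack_parameters,
)
from visconf.models import (
    ModelSpec,
    ParameterError,
    ParameterSet,
    count_free_parameters,
    predict_response_probabilities,
)
from visconf.models.simulate import simulate_trials
from visconf.synthetic import sample_parameters

from conftest import all_specs, draw_params

QUICK = FitSettings(n_starts=2, n_restarts=1, max_iter=150)


class TestInformationCriteria:
    def test_aicc_closed_form(self):
        assert np.isclose(aicc(0.0, 2, 10), 4 + 12 / 7)

    def test_bic_closed_form(self):
        assert np.isclose(bic(0.0, 2, 100), 2 * np.log(100))

    def test_aicc_correction_vanishes_for_large_n(self):
        negll, k = 123.4, 16
        assert abs(aicc(negll, k, 10**7) - (2 * negll + 2 * k)) < 1e-3

    def test_aicc_requires_enough_trials(self):
        with pytest.raises(ValueError):
            aicc(1.0, 10, 11)


class TestFreeParameterCounts:
    @pytest.mark.parametrize(
        "family,expected",
        [
            ("sdt", 14),
            ("noisy_sdt", 15),
            ("wev", 16),
            ("two_channel", 15),
            ("postdecisional", 15),
            ("cnd", 20),
            ("rce", 14),
            ("bayes2d", 11),
        ],
    )
    def test_constant_variance_counts(self, family, expected):
        assert count_free_parameters(ModelSpec(family), EXP1_DESIGN) == expected

    def test_variance_modes_add_one(self):
        for family in ("sdt", "wev", "cnd"):
            base = count_free_parameters(ModelSpec(family), EXP1_DESIGN)
            for mode in ("identity_dependent", "soa_dependent"):
                assert count_free_parameters(ModelSpec(family, mode), EXP1_DESIGN) == base + 1


class TestNegativeLogLikelihood:
    def test_empty_counts_give_zero(self):
        spec = ModelSpec("sdt")
        params = draw_params(spec, 0)
        counts = CountTable(EXP1_DESIGN)
        assert negative_log_likelihood(spec, params, counts) == 0.0

    def test_uniform_cells_closed_form(self):
        """10 trials uniformly spread over 10 equiprobable cells -> 10 ln 10."""
        design = ExperimentDesign(soa_levels_ms=(8.3,), trials_per_soa=10)
        spec = ModelSpec("bayes2d")
        # full lapse -> every joint response uniformly likely (p = 1/10)
        params = ParameterSet(s_noise=30.0, lam=1.0, theta_post=np.arange(1, 10) / 10.0)
        table = predict_response_probabilities(spec, params, design)
        np.testing.assert_allclose(table.p, 0.1, atol=1e-12)
        counts = CountTable(design, np.zeros((2, 1, 2, 5), dtype=int))
        counts.counts[0, 0] = np.ones((2, 5), dtype=int)
        assert np.isclose(
            negative_log_likelihood(spec, params, counts), 10 * np.log(10), rtol=1e-12
        )

    def test_equals_per_trial_summation(self):
        """Count-weighted form must equal trial-by-trial log-probability sums."""
        spec = ModelSpec("wev")
        params = draw_params(spec, 3)
        trials = simulate_trials(spec, params, EXP1_DESIGN, seed=9)
        counts = tabulate(trials, EXP1_DESIGN)
        table = predict_response_probabilities(spec, params, EXP1_DESIGN)
        per_trial = 0.0
        for _, row in trials.iterrows():
            si = (row.stimulus + 1) // 2
            ti = int(EXP1_DESIGN.soa_index([row.soa_ms])[0])
            ri = (row.response + 1) // 2
            per_trial -= np.log(max(table.p[si, ti, ri, row.category], 1e-10))
        assert np.isclose(negative_log_likelihood(spec, params, counts), per_trial, rtol=1e-10)

    def test_invalid_parameters_raise_before_numerics(self):
        spec = ModelSpec("wev")
        params = draw_params(spec, 0)
        params.w = 1.5
        with pytest.raises(ParameterError):
            negative_log_likelihood(spec, params, CountTable(EXP1_DESIGN))


class TestParameterTransforms:
    @pytest.mark.parametrize("spec", all_specs(include_modes=True), ids=lambda s: s.label())
    def test_pack_unpack_round_trip(self, spec):
        params = draw_params(spec, 17)
        x = pack_parameters(spec, params, EXP1_DESIGN)
        back = unpack_parameters(spec, x, EXP1_DESIGN)
        for name in (
            "s_s", "theta_id", "theta_v_minus", "theta_v_plus", "sigma_v", "w", "a", "b",
            "rho", "s_noise", "lam", "theta_post", "r_id", "k",
        ):
            v, u = getattr(params, name), getattr(back, name)
            if v is None:
                assert u is None
            else:
                np.testing.assert_allclose(u, v, rtol=1e-8, atol=1e-10)

    def test_unpack_always_valid(self):
        from visconf.models import validate_parameters

        rng = np.random.default_rng(1)
        for spec in all_specs():
            n = len(pack_parameters(spec, draw_params(spec, 2), EXP1_DESIGN))
            for _ in range(20):
                x = rng.normal(0, 3, size=n)
                validate_parameters(spec, unpack_parameters(spec, x, EXP1_DESIGN), EXP1_DESIGN)


class TestFitModel:
    def test_deterministic_given_settings(self, tiny_design):
        spec = ModelSpec("noisy_sdt")
        params = draw_params(spec, 4, tiny_design)
        trials = simulate_trials(spec, params, tiny_design, seed=2)
        counts = tabulate(trials, tiny_design)
        settings = FitSettings(n_starts=2, n_restarts=1, max_iter=60)
        f1 = fit_model(spec, counts, settings, tiny_design)
        f2 = fit_model(spec, counts, settings, tiny_design)
        assert f1.neg_log_likelihood == f2.neg_log_likelihood
        np.testing.assert_array_equal(f1.params.s_s, f2.params.s_s)
        np.testing.assert_array_equal(f1.params.theta_v_plus, f2.params.theta_v_plus)

    def test_fit_beats_truth_and_grid(self):
        """ML optimality: fitted negLL <= negLL at the generating parameters,
        and simplex refinement never loses to the best grid candidate."""
        spec = ModelSpec("wev")
        truth = draw_params(spec, 21)
        trials = simulate_trials(spec, truth, EXP1_DESIGN, seed=21)
        counts = tabulate(trials, EXP1_DESIGN)
        fit = fit_model(spec, counts, QUICK, EXP1_DESIGN)
        assert fit.neg_log_likelihood <= negative_log_likelihood(spec, truth, counts) + 1e-6
        best_grid = fit.optimizer_trace[0][1]
        assert fit.neg_log_likelihood <= best_grid + 1e-6
        assert fit.k_free == count_free_parameters(spec, EXP1_DESIGN)
        assert np.isclose(fit.aicc, aicc(fit.neg_log_likelihood, fit.k_free, 550))

    def test_recovers_sdt_sensitivity_at_large_n(self):
        """Fitted per-SOA sensitivities within +/-0.15 of truth at n=5000/SOA."""
        design = ExperimentDesign(trials_per_soa=5000)
        spec = ModelSpec("sdt")
        truth = draw_params(spec, 33, design)
        trials = simulate_trials(spec, truth, design, seed=33)
        counts = tabulate(trials, design)
        fit = fit_model(spec, counts, QUICK, design)
        assert np.all(np.abs(fit.params.s_s - truth.s_s) < 0.15)

    def test_rejects_empty_counts(self):
        from visconf.fitting import FitError

        with pytest.raises(FitError):
            fit_model(ModelSpec("sdt"), CountTable(EXP1_DESIGN), QUICK, EXP1_DESIGN)


class TestIdentifiability:
    """On expected-frequency data the generative family cannot lose.

    For each family, counts are the (rounded) expected frequencies at a known
    parameter set and a large trial count; cross-entropy is minimized by the
    true distribution, so the generative family evaluated at truth must fit
    at least as well as any fitted competitor (up to rounding slack).
    """

    @pytest.mark.parametrize("family", ["sdt", "noisy_sdt", "wev", "two_channel",
                                        "postdecisional", "cnd", "rce", "bayes2d"])
    def test_generative_family_wins_on_its_own_expected_data(self, family):
        design = ExperimentDesign(trials_per_soa=2000)
        spec = ModelSpec(family)
        truth = draw_params(spec, 55, design)
        table = predict_response_probabilities(spec, truth, design)
        n_minus, n_plus = design.trials_per_identity()
        expected = table.p * np.array([n_minus, n_plus])[:, None, None, None]
        counts = CountTable(design, np.round(expected).astype(int))
        negll_truth = negative_log_likelihood(spec, truth, counts)
        competitor = "wev" if family != "wev" else "noisy_sdt"
        comp_fit = fit_model(ModelSpec(competitor), counts, QUICK, design)
        assert negll_truth <= comp_fit.neg_log_likelihood + 2.0
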