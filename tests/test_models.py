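import numpy as np
import pytest
from scipy.stats import norm

from visconf.data_model import EXP1_DESIGN
from visconf.models import (
    ModelSpec,
    ParameterError,
    ParameterSet,
    posterior_identity,
    predict_response_probabilities,
    sigma_id_of,
)
from visconf.models.simulate import simulate_condition_categories, simulate_trials
from visconf.synthetic import sample_parameters

from conftest import all_specs, draw_params


def base_params(**extra):
    return ParameterSet(
        s_s=[0.1, 0.6, 1.5, 2.6, 3.9],
        theta_id=0.1,
        theta_v_plus=[-0.3, 0.3, 0.9, 1.6],
        theta_v_minus=[0.3, -0.3, -0.9, -1.6],
        **extra,
    )


class TestSigmaId:
    def test_constant_is_unity(self):
        assert float(sigma_id_of("constant", ParameterSet(), 1, 2.0)) == 1.0

    def test_identity_dependent_power(self):
        p = ParameterSet(r_id=1.0)
        assert float(sigma_id_of("identity_dependent", p, -1, 3.0)) == 1.0
        p = ParameterSet(r_id=1.3)
        assert np.isclose(float(sigma_id_of("identity_dependent", p, -1, 3.0)), 1 / 1.3)

    def test_soa_dependent_sqrt_law(self):
        p = ParameterSet(k=0.0)
        assert float(sigma_id_of("soa_dependent", p, 1, 3.0)) == 1.0
        p = ParameterSet(k=0.5)
        assert np.isclose(float(sigma_id_of("soa_dependent", p, 1, 2.0)), np.sqrt(3.0))

    def test_invalid_mode_parameters(self):
        with pytest.raises(ParameterError):
            sigma_id_of("soa_dependent", ParameterSet(k=-1.0), 1, 2.0)


class TestStructure:
    def test_bayes2d_rejects_variance_modes(self):
        with pytest.raises(ParameterError):
            ModelSpec("bayes2d", "soa_dependent")

    def test_invalid_criteria_order_rejected(self):
        spec = ModelSpec("sdt")
        p = base_params()
        p.theta_v_plus = np.array([0.3, -0.3, 0.9, 1.6])
        with pytest.raises(ParameterError):
            predict_response_probabilities(spec, p, EXP1_DESIGN)


class TestNormalization:
    @pytest.mark.parametrize("spec", all_specs(include_modes=True), ids=lambda s: s.label())
    def test_sampled_parameter_sets_normalize(self, spec):
        for i in range(10):
            params = draw_params(spec, 1000 + i)
            table = predict_response_probabilities(spec, params, EXP1_DESIGN, check=False)
            assert np.all(table.p >= -1e-12)
            np.testing.assert_allclose(table.p.sum(axis=(2, 3)), 1.0, atol=1e-6)


class TestReductions:
    def test_wev_with_zero_weight_equals_noisy_sdt(self):
        p_wev = base_params(sigma_v=0.8, w=0.0)
        p_noisy = base_params(sigma_v=0.8)
        t1 = predict_response_probabilities(ModelSpec("wev"), p_wev, EXP1_DESIGN)
        t2 = predict_response_probabilities(ModelSpec("noisy_sdt"), p_noisy, EXP1_DESIGN)
        np.testing.assert_allclose(t1.p, t2.p, atol=1e-8)

    @pytest.mark.parametrize(
        "family,extra",
        [
            ("noisy_sdt", dict(sigma_v=1e-4)),
            ("postdecisional", dict(b=1e-6)),
            ("cnd", dict(sigma_v=1e-4, rho=np.ones(5))),
        ],
    )
    def test_families_collapse_to_sdt(self, family, extra):
        p = base_params(**extra)
        t1 = predict_response_probabilities(ModelSpec(family), p, EXP1_DESIGN, n_nodes=121)
        t2 = predict_response_probabilities(ModelSpec("sdt"), base_params(), EXP1_DESIGN)
        np.testing.assert_allclose(t1.p, t2.p, atol=1e-4)


class TestSdtStructure:
    def test_symmetric_zero_strength_gives_half(self):
        p = ParameterSet(
            s_s=np.zeros(5),
            theta_id=0.0,
            theta_v_plus=[0.3, 0.8, 1.3, 1.8],
            theta_v_minus=[-0.3, -0.8, -1.3, -1.8],
        )
        table = predict_response_probabilities(ModelSpec("sdt"), p, EXP1_DESIGN)
        np.testing.assert_allclose(table.p[:, :, 1, :].sum(axis=-1), 0.5, atol=1e-12)

    def test_accuracy_monotone_in_strength(self):
        for family, extra in (("sdt", {}), ("wev", dict(sigma_v=0.8, w=0.4))):
            p = base_params(**extra)
            p.s_s = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
            table = predict_response_probabilities(ModelSpec(family), p, EXP1_DESIGN)
            p_correct = 0.5 * (
                table.p[0, :, 0, :].sum(axis=-1) + table.p[1, :, 1, :].sum(axis=-1)
            )
            assert np.all(np.diff(p_correct) > -1e-9)

    def test_high_strength_reaches_ceiling(self):
        p = base_params()
        p.s_s = np.array([0.1, 0.5, 1.0, 2.0, 8.0])
        trials = simulate_trials(ModelSpec("sdt"), p, EXP1_DESIGN, seed=1)
        top = trials[trials.soa_ms == 133.3]
        assert (top.response == top.stimulus).mean() > 0.99


class TestPosteriorIdentity:
    def test_exchangeable_inputs_give_half(self):
        soas = EXP1_DESIGN.soa_levels_ms
        for v in (-3.0, 0.0, 20.0):
            assert np.isclose(posterior_identity(v, v, 30.0, soas), 0.5, atol=1e-12)

    def test_vanishing_noise_limit(self):
        soas = EXP1_DESIGN.soa_levels_ms
        val = posterior_identity(0.0, 133.3, 0.5, soas)
        assert val > 1 - 1e-10

    def test_matches_explicit_double_sum(self):
        """Hand-computed two-SOA double sum as the oracle."""
        soa_set = (1.0, 2.0)
        d_minus, d_plus, s = 1.0, 2.0, 1.0
        num = sum(norm.pdf(d_minus, 0, s) * norm.pdf(d_plus, t, s) for t in soa_set)
        den = num + sum(norm.pdf(d_minus, t, s) * norm.pdf(d_plus, 0, s) for t in soa_set)
        expected = num / den
        assert np.isclose(posterior_identity(d_minus, d_plus, s, soa_set), expected, atol=1e-12)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ParameterError):
            posterior_identity(0.0, 1.0, -1.0, (1.0, 2.0))
        with pytest.raises(ParameterError):
            posterior_identity(0.0, 1.0, 1.0, ())


class TestSimulatorAgreement:
    """The simulator samples latent variables; the likelihood integrates them.

    Agreement between the two independent code paths is checked at moderate
    Monte-Carlo size here (the full-size check runs in the acceptance suite,
    which also covers every family under constant variance).
    """

    @pytest.mark.parametrize(
        "spec",
        [
            ModelSpec("wev", "identity_dependent"),
            ModelSpec("rce", "soa_dependent"),
            ModelSpec("postdecisional", "identity_dependent"),
            ModelSpec("cnd", "soa_dependent"),
            ModelSpec("two_channel", "soa_dependent"),
        ],
        ids=lambda s: s.label(),
    )
    def test_variance_mode_simulator_matches_likelihood(self, spec):
        params = draw_params(spec, 99)
        table = predict_response_probabilities(spec, params, EXP1_DESIGN)
        rng = np.random.default_rng(77)
        n = 100_000
        for si, s_id in enumerate((-1, 1)):
            for ti in (0, 2, 4):
                r, cat = simulate_condition_categories(spec, params, EXP1_DESIGN, s_id, ti, n, rng)
                emp = np.zeros((2, EXP1_DESIGN.n_categories))
                np.add.at(emp, ((r + 1) // 2, cat), 1.0)
                emp /= n
                se = np.sqrt(np.maximum(table.p[si, ti] * (1 - table.p[si, ti]), 1e-12) / n)
                z = np.abs(emp - table.p[si, ti]) / np.maximum(se, 1e-9)
                assert z.max() < 5.0

    def test_simulation_is_deterministic_under_seed(self):
        spec = ModelSpec("bayes2d")
        params = draw_params(spec, 5)
        t1 = simulate_trials(spec, params, EXP1_DESIGN, seed=123)
        t2 = simulate_trials(spec, params, EXP1_DESIGN, seed=123)
        assert t1.equals(t2)
        t3 = simulate_trials(spec, params, EXP1_DESIGN, seed=124)
        assert not t1.equals(t3)
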