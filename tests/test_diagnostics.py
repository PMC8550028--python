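import itertools

import numpy as np
import pandas as pd
import pytest

from visconf.data_model import EXP1_DESIGN, ExperimentDesign
from visconf.diagnostics import (
    contingency_20,
    gamma_by_accuracy,
    gamma_from_table,
    goodman_kruskal_gamma,
    predicted_gamma,
)
from visconf.models import ModelSpec, ParameterSet, simulate_trials
from visconf.synthetic import generate_joint, sample_parameters


def gamma_by_pair_enumeration(x, y):
    c = d = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            s = (x[i] - x[j]) * (y[i] - y[j])
            c += s > 0
            d += s < 0
    return float("nan") if c + d == 0 else (c - d) / (c + d)


class TestGoodmanKruskalGamma:
    @pytest.mark.parametrize(
        "x,y,expected",
        [((1, 2, 3), (1, 2, 3), 1.0), ((1, 2, 3), (3, 2, 1), -1.0), ((1, 2, 3), (1, 2, 1), 0.0)],
    )
    def test_known_values(self, x, y, expected):
        assert goodman_kruskal_gamma(x, y) == pytest.approx(expected)

    def test_all_ties_is_nan(self):
        assert np.isnan(goodman_kruskal_gamma([1, 1, 1], [1, 2, 3]))

    def test_matches_pair_enumeration_on_short_vectors(self):
        for n in (2, 3, 4):
            for x in itertools.product(range(3), repeat=n):
                for y in itertools.product(range(3), repeat=n):
                    got = goodman_kruskal_gamma(list(x), list(y))
                    want = gamma_by_pair_enumeration(x, y)
                    assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)

    def test_antisymmetric_under_order_reversal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, 30)
            y = rng.integers(0, 5, 30)
            g1 = goodman_kruskal_gamma(x, y)
            g2 = goodman_kruskal_gamma(x, -y)
            if np.isnan(g1):
                assert np.isnan(g2)
            else:
                assert g1 == pytest.approx(-g2)

    def test_fractional_table_matches_scaled_integer_table(self):
        rng = np.random.default_rng(1)
        w = rng.integers(0, 6, size=(4, 5)).astype(float)
        g1, _ = gamma_from_table(w)
        g2, _ = gamma_from_table(w * 0.137)
        assert g1 == pytest.approx(g2)


class TestGammaByAccuracy:
    def test_perfect_concordance_and_undefined_subset(self):
        df = pd.DataFrame(
            {
                "soa_ms": list(EXP1_DESIGN.soa_levels_ms),
                "stimulus": [1] * 5,
                "response": [1] * 5,
                "category": [0, 1, 2, 3, 4],
            }
        )
        res = gamma_by_accuracy(df, EXP1_DESIGN)
        assert res.gamma_correct == pytest.approx(1.0)
        assert np.isnan(res.gamma_incorrect)

    def test_shuffled_categories_center_on_zero(self):
        """Permutation oracle: association vanishes under label shuffling."""
        spec = ModelSpec("wev")
        params = sample_parameters(spec, 8)
        trials = simulate_trials(spec, params, EXP1_DESIGN, seed=8)
        rng = np.random.default_rng(0)
        gammas = []
        for _ in range(100):
            shuffled = trials.copy()
            shuffled["category"] = rng.permutation(shuffled["category"].to_numpy())
            gammas.append(gamma_by_accuracy(shuffled, EXP1_DESIGN).gamma_correct)
        assert abs(np.mean(gammas)) < 0.05

    def test_wev_keeps_positive_association_on_errors(self):
        """Strength-sensitive reports stay correlated with SOA on incorrect trials."""
        spec = ModelSpec("wev")
        params = sample_parameters(spec, 8, ranges={"w": (0.6, 0.6)})
        trials = simulate_trials(spec, params, EXP1_DESIGN, seed=8)
        res = gamma_by_accuracy(trials, EXP1_DESIGN)
        assert res.gamma_incorrect > 0.1


class TestPredictedGamma:
    def test_soa_exchangeable_model_gives_zero(self):
        params = ParameterSet(
            s_s=np.full(5, 1.5),
            theta_id=0.0,
            theta_v_plus=[-0.3, 0.3, 0.9, 1.6],
            theta_v_minus=[0.3, -0.3, -0.9, -1.6],
        )
        res = predicted_gamma(ModelSpec("sdt"), params, EXP1_DESIGN)
        assert res.gamma_correct == pytest.approx(0.0, abs=1e-10)
        assert res.gamma_incorrect == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_large_simulation(self):
        """Expected-count gamma must match the trial-level statistic at scale."""
        spec = ModelSpec("wev")
        params = sample_parameters(spec, 13)
        pred = predicted_gamma(spec, params, EXP1_DESIGN)
        big = ExperimentDesign(trials_per_soa=200_000)
        trials = simulate_trials(spec, params, big, seed=99)
        obs = gamma_by_accuracy(trials, big)
        assert obs.gamma_correct == pytest.approx(pred.gamma_correct, abs=0.01)
        assert obs.gamma_incorrect == pytest.approx(pred.gamma_incorrect, abs=0.01)

    def test_wev_exceeds_sdt_on_incorrect_trials(self):
        base = dict(
            s_s=[0.1, 0.6, 1.5, 2.6, 3.9],
            theta_id=0.0,
            theta_v_plus=[-0.3, 0.3, 0.9, 1.6],
            theta_v_minus=[0.3, -0.3, -0.9, -1.6],
        )
        g_sdt = predicted_gamma(ModelSpec("sdt"), ParameterSet(**base), EXP1_DESIGN)
        g_wev = predicted_gamma(
            ModelSpec("wev"), ParameterSet(**base, sigma_v=0.8, w=0.5), EXP1_DESIGN
        )
        assert g_wev.gamma_incorrect > g_sdt.gamma_incorrect


class TestContingency20:
    def test_identical_judgments_never_dissociate(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 1, 2000)
        df = pd.DataFrame({"visibility": r, "confidence": r})
        res = contingency_20(df)
        assert res.p_vis_given_lowconf == 0.0
        assert res.p_conf_given_lowvis == 0.0

    def test_independent_uniform_ratings(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"visibility": rng.uniform(0, 1, 50_000), "confidence": rng.uniform(0, 1, 50_000)}
        )
        res = contingency_20(df)
        assert res.p_vis_given_lowconf == pytest.approx(0.8, abs=0.01)
        assert res.p_conf_given_lowvis == pytest.approx(0.8, abs=0.01)

    def test_threshold_values_count_as_not_below(self):
        df = pd.DataFrame({"visibility": [0.2, 0.1], "confidence": [0.1, 0.2]})
        res = contingency_20(df)
        # rating exactly 0.2 is neither "below" nor "above" the threshold
        assert res.p_vis_given_lowconf == 0.0
        assert res.p_conf_given_lowvis == 0.0

    def test_empty_conditioning_sets_are_excluded(self):
        df = pd.DataFrame(
            {
                "participant": ["a"] * 3 + ["b"] * 3,
                "visibility": [0.9, 0.8, 0.9, 0.1, 0.5, 0.9],
                "confidence": [0.9, 0.8, 0.7, 0.1, 0.6, 0.8],
            }
        )
        res = contingency_20(df)
        assert res.n_excluded_vis == 1 and res.n_excluded_conf == 1

    def test_weight_asymmetry_reproduces_dissociation_direction(self):
        """A larger strength weight for visibility than confidence makes
        confidence-without-visibility the more common dissociation."""
        params = sample_parameters("wev", 3)
        trials = generate_joint(
            params, w_vis=0.55, w_conf=0.25, n_trials_per_condition=20_000, seed=5
        )
        res = contingency_20(trials)
        assert res.p_conf_given_lowvis > res.p_vis_given_lowconf
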