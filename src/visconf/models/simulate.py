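"""Trial simulators: sample each family's latent variables per its equations.

The simulators draw the latent decision variables directly (never the
likelihood's probability table), so they are an independent implementation
against which the quadrature likelihoods are cross-validated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from ..data_model import ExperimentDesign
from .families import (
    ModelSpec,
    ParameterSet,
    rating_edges,
    sigma_id_of,
    validate_parameters,
)

__all__ = ["simulate_trials", "simulate_condition_categories"]


def _categorize(delta_v, r_sign, edges_minus, edges_plus, orient_minus):
    """Map report values to categories under the per-response criteria sets."""
    cat = np.empty(delta_v.shape, dtype=int)
    plus = r_sign > 0
    cat[plus] = np.searchsorted(edges_plus, delta_v[plus], side="right")
    cat[~plus] = np.searchsorted(edges_minus, orient_minus * delta_v[~plus], side="right")
    return cat


def _explicit_posterior(d_minus, d_plus, s_noise, soas):
    """Eq.-style posterior by literal double summation over SOAs x identities."""
    num = np.zeros_like(d_minus)
    den = np.zeros_like(d_minus)
    for t in soas:
        num += norm.pdf(d_minus, 0.0, s_noise) * norm.pdf(d_plus, t, s_noise)
        den += norm.pdf(d_minus, t, s_noise) * norm.pdf(d_plus, 0.0, s_noise)
    total = num + den
    # vanishing densities at extreme draws: decide by the nearer identity mean
    degenerate = total <= 0
    post = np.where(degenerate, (d_plus > d_minus).astype(float), num / np.where(total > 0, total, 1.0))
    return post


def simulate_condition_categories(
    spec: ModelSpec,
    params: ParameterSet,
    design: ExperimentDesign,
    s_id: int,
    soa_index: int,
    n: int,
    rng: np.random.Generator,
):
    """Draw ``n`` trials of one (stimulus, SOA) condition.

    Returns ``(responses, categories)`` with responses in {-1, +1}.
    """
    strength = None if spec.family == "bayes2d" else float(params.s_s[soa_index])
    soa = design.soa_levels_ms[soa_index]
    fam = spec.family

    if fam == "bayes2d":
        s = params.s_noise
        mu_m = 0.5 * (1.0 - s_id) * soa
        mu_p = 0.5 * (1.0 + s_id) * soa
        d_minus = rng.normal(mu_m, s, size=n)
        d_plus = rng.normal(mu_p, s, size=n)
        post = _explicit_posterior(d_minus, d_plus, s, np.asarray(design.soa_levels_ms))
        option = np.searchsorted(np.asarray(params.theta_post), post, side="right")
        lapse = rng.random(n) < params.lam
        option[lapse] = rng.integers(0, 2 * design.n_categories, size=int(lapse.sum()))
        n_cat = design.n_categories
        r = np.where(option < n_cat, -1, 1)
        cat = np.where(option < n_cat, n_cat - 1 - option, option - n_cat)
        return r, cat

    sigma = float(sigma_id_of(spec.variance_mode, params, s_id, strength))
    edges_minus, edges_plus, orient_minus = rating_edges(spec, params)

    if fam == "rce":
        mu_m = 0.5 * (1.0 - s_id) * strength - params.theta_id
        mu_p = 0.5 * (1.0 + s_id) * strength + params.theta_id
        d_m = rng.normal(mu_m, sigma, size=n)
        d_p = rng.normal(mu_p, sigma, size=n)
        r = np.where(d_m > d_p, -1, 1)
        winner = np.where(r < 0, d_m, d_p)
        cat = np.empty(n, dtype=int)
        cat[r < 0] = np.searchsorted(edges_minus, winner[r < 0], side="right")
        cat[r > 0] = np.searchsorted(edges_plus, winner[r > 0], side="right")
        return r, cat

    mu = 0.5 * s_id * strength
    delta_id = rng.normal(mu, sigma, size=n)
    r = np.where(delta_id < params.theta_id, -1, 1)
    if fam == "sdt":
        delta_v = delta_id
    elif fam == "noisy_sdt":
        delta_v = rng.normal(delta_id, params.sigma_v)
    elif fam == "wev":
        mean = (1.0 - params.w) * delta_id + params.w * r * (strength - params.mean_strength)
        delta_v = rng.normal(mean, params.sigma_v)
    elif fam == "two_channel":
        delta_v = rng.normal(0.5 * s_id * strength * params.a, 1.0, size=n)
    elif fam == "postdecisional":
        delta_v = rng.normal(delta_id + s_id * strength * params.b, np.sqrt(params.b))
    elif fam == "cnd":
        delta_v = rng.normal(params.rho[soa_index] * delta_id, params.sigma_v)
    else:  # pragma: no cover
        raise ValueError(fam)
    cat = _categorize(delta_v, r, edges_minus, edges_plus, orient_minus)
    return r, cat


def simulate_trials(
    spec: ModelSpec,
    params: ParameterSet,
    design: ExperimentDesign | None = None,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    judgment_type: str = "visibility",
) -> pd.DataFrame:
    """Simulate a full experiment for one observer.

    Trial counts follow the design (``trials_per_soa`` per SOA, split as
    evenly as possible between the two stimulus identities). Deterministic
    given the seed.
    """
    design = design or ExperimentDesign()
    validate_parameters(spec, params, design)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_minus, n_plus = design.trials_per_identity()
    frames = []
    for ti, soa in enumerate(design.soa_levels_ms):
        for s_id, n in ((-1, n_minus), (1, n_plus)):
            if n == 0:
                continue
            r, cat = simulate_condition_categories(spec, params, design, s_id, ti, n, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "participant": participant_id,
                        "soa_ms": soa,
                        "stimulus": s_id,
                        "response": r,
                        "category": cat,
                        "judgment": judgment_type,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["participant", "soa_ms", "stimulus", "response", "category", "judgment"]
        )
    return pd.concat(frames, ignore_index=True)
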