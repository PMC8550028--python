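"""Exact response-probability tables P(R_id, R_v | S_id, SOA) for all families.

Every family reduces to closed forms or smooth one-dimensional integrals:

* the SDT rating and two-channel families are closed-form Gaussian-CDF
  differences;
* families whose report variable is a noisy linear function of the
  identification variable (noisy SDT, WEV, postdecisional accumulation,
  constant noise and decay) have jointly Gaussian (delta_id, delta_v), so
  each joint cell is an exact bivariate-normal rectangle probability,
  evaluated through Owen's T function — exact even in the degenerate
  small-report-noise limit;
* the response-congruent-evidence family integrates the winning channel's
  density times the losing channel's CDF over each rating bin, by the
  probability-space substitution x = mu + sigma * ndtri(p) and Gauss-Legendre
  quadrature on the exact per-bin probability range (a smooth integrand);
* the 2D Bayesian family is reduced exactly to one dimension: its posterior
  equals expit(H(delta_plus) - H(delta_minus)) with the strictly increasing
  H(x) = logsumexp_t((x*t - t^2/2) / s^2), so each posterior-criterion band
  is an interval in delta_plus whose endpoints are found by inverting H.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit, logit, logsumexp, ndtr, ndtri, owens_t

from ..data_model import ExperimentDesign
from .families import (
    ModelSpec,
    ParameterError,
    ParameterSet,
    rating_edges,
    sigma_id_of,
    validate_parameters,
)

__all__ = [
    "ConditionProbabilityTable",
    "predict_response_probabilities",
    "posterior_identity",
    "probability_table_frame",
]

_P_EPS = 1e-15  # clip for probability-space nodes fed to ndtri


@lru_cache(maxsize=8)
def _leggauss01(n: int):
    """Gauss-Legendre nodes/weights transplanted to (0, 1)."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


@dataclass
class ConditionProbabilityTable:
    """Joint response probabilities indexed by (stimulus, SOA, response, category)."""

    design: ExperimentDesign
    p: np.ndarray

    def check_normalization(self, tol: float = 1e-6):
        total = self.p.sum(axis=(2, 3))
        err = float(np.max(np.abs(total - 1.0)))
        if err > tol:
            raise FloatingPointError(
                f"condition probabilities sum to 1 +/- {err:.2e} (tolerance {tol:g})"
            )
        return self


def _bin_probs(y, edges, sd):
    """P(category | report ~ N(y, sd)) for increasing bin edges; shape (..., n_cat)."""
    z = (edges.reshape((1,) * y.ndim + (-1,)) - y[..., None]) / sd
    cdf = ndtr(z)
    lo = np.concatenate([np.zeros_like(cdf[..., :1]), cdf], axis=-1)
    hi = np.concatenate([cdf, np.ones_like(cdf[..., :1])], axis=-1)
    return hi - lo


def _interval_prob(mu, sigma, lo, hi):
    """Gaussian probability of [lo, hi] with broadcasting; empty intervals -> 0."""
    p = ndtr((hi - mu) / sigma) - ndtr((lo - mu) / sigma)
    return np.clip(p, 0.0, 1.0)


def _condition_grid(params: ParameterSet, spec: ModelSpec, design: ExperimentDesign):
    s_id = np.array([-1.0, 1.0])[:, None]  # (2, 1)
    strength = np.asarray(params.s_s, dtype=float)[None, :]  # (1, T)
    mu = 0.5 * s_id * strength
    sigma = sigma_id_of(spec.variance_mode, params, s_id, strength)
    return s_id, strength, np.broadcast_to(mu, (2, design.n_soa)), np.broadcast_to(
        sigma, (2, design.n_soa)
    )


def _predict_sdt(spec, params, design):
    """Closed form: the report variable is the identification variable itself."""
    s_id, strength, mu, sigma = _condition_grid(params, spec, design)
    e_minus, e_plus, _ = rating_edges(spec, params)
    theta = params.theta_id
    n_cat = design.n_categories
    p = np.zeros((2, design.n_soa, 2, n_cat))
    big = 1e30
    # R_id = +1: delta_id in [theta, inf); bins from e_plus on delta_id.
    bounds = np.concatenate([[-big], e_plus, [big]])
    for v in range(n_cat):
        lo = max(bounds[v], theta)
        hi = max(bounds[v + 1], theta)
        p[:, :, 1, v] = _interval_prob(mu, sigma, lo, hi)
    # R_id = -1: mirrored axis y = -delta_id, y-mean -mu, region y > -theta.
    bounds = np.concatenate([[-big], e_minus, [big]])
    for v in range(n_cat):
        lo = max(bounds[v], -theta)
        hi = max(bounds[v + 1], -theta)
        p[:, :, 0, v] = _interval_prob(-mu, sigma, lo, hi)
    return p


def _predict_two_channel(spec, params, design):
    s_id, strength, mu, sigma = _condition_grid(params, spec, design)
    e_minus, e_plus, orient_minus = rating_edges(spec, params)
    p_plus = 1.0 - ndtr((params.theta_id - mu) / sigma)
    mu_v = 0.5 * s_id * strength * params.a  # second channel, unit sd
    p = np.zeros((2, design.n_soa, 2, design.n_categories))
    p[:, :, 1, :] = p_plus[..., None] * _bin_probs(mu_v, e_plus, 1.0)
    p[:, :, 0, :] = (1.0 - p_plus)[..., None] * _bin_probs(orient_minus * mu_v, e_minus, 1.0)
    return p


def _report_coefficients(spec, params, s_id, strength, r_sign):
    """Mean of the report variable as alpha * delta_id + beta; returns (alpha, beta, sd).

    ``alpha`` and ``beta`` broadcast against the (stimulus, SOA) condition grid.
    """
    fam = spec.family
    if fam == "noisy_sdt":
        return 1.0, 0.0, params.sigma_v
    if fam == "wev":
        return 1.0 - params.w, params.w * r_sign * (strength - params.mean_strength), params.sigma_v
    if fam == "cnd":
        return params.rho[None, :], 0.0, params.sigma_v
    if fam == "postdecisional":
        return 1.0, s_id * strength * params.b, float(np.sqrt(params.b))
    raise ParameterError(f"family '{fam}' has no linear report form")


def _bvn_cdf(h, k, rho, sqrt_1m_rho2):
    """Standard bivariate normal P(X <= h, Y <= k) via Owen's T function.

    ``sqrt_1m_rho2`` is supplied by the caller from exact variance algebra to
    avoid catastrophic cancellation when |rho| approaches 1.
    """
    # nudge exact zeros so the Owen decomposition's divisions are defined
    h = np.where(np.abs(h) < 1e-13, 1e-13, h)
    k = np.where(np.abs(k) < 1e-13, 1e-13, k)
    denom = np.maximum(sqrt_1m_rho2, 1e-300)
    a1 = np.clip((k / h - rho) / denom, -1e10, 1e10)
    a2 = np.clip((h / k - rho) / denom, -1e10, 1e10)
    beta = np.where(h * k < 0, 0.5, 0.0)
    return 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a1) - owens_t(k, a2) - beta


def _predict_truncated_linear(spec, params, design, n_nodes):
    """Noisy SDT / WEV / postdecisional / constant-noise-and-decay likelihoods.

    The identification variable and the report variable are jointly Gaussian
    (the report mean is linear in delta_id), so each joint cell
    P(R_id, R_v = v) is an exact bivariate-normal rectangle probability;
    no quadrature is involved.
    """
    s_id, strength, mu, sigma = _condition_grid(params, spec, design)
    e_minus, e_plus, orient_minus = rating_edges(spec, params)
    h = (params.theta_id - mu) / sigma  # (2, T)
    q0 = ndtr(h)  # P(R_id = -1 | condition)
    # leading axis: response (-1, +1); one Owen's-T batch covers both
    cond = (2, design.n_soa)
    al_m, be_m, sv = _report_coefficients(spec, params, s_id, strength, -1.0)
    al_p, be_p, _ = _report_coefficients(spec, params, s_id, strength, 1.0)
    alpha = np.stack([np.broadcast_to(al_m, cond), np.broadcast_to(al_p, cond)])
    beta = np.stack([np.broadcast_to(be_m, cond), np.broadcast_to(be_p, cond)])
    orient = np.array([orient_minus, 1.0])[:, None, None]
    sigma_tot = np.sqrt((alpha * sigma) ** 2 + sv**2)
    rho = orient * alpha * sigma / sigma_tot
    sqrt_1m_rho2 = sv / sigma_tot  # exact: 1 - rho^2 = sv^2 / sigma_tot^2
    mean_y = orient * (alpha * mu + beta)
    edges = np.stack([e_minus, e_plus])[:, None, None, :]  # (2, 1, 1, E)
    k = (edges - mean_y[..., None]) / sigma_tot[..., None]  # (2, 2, T, E)
    phi2 = _bvn_cdf(
        np.broadcast_to(h[None, ..., None], k.shape), k, rho[..., None], sqrt_1m_rho2[..., None]
    )
    # response -1: P(X <= h, Y' <= edge); response +1: P(X > h, Y' <= edge)
    cum = np.clip(np.stack([phi2[0], ndtr(k[1]) - phi2[1]]), 0.0, 1.0)
    total = np.stack([q0, 1.0 - q0])[..., None]
    cum = np.minimum(np.maximum.accumulate(cum, axis=-1), total)
    lo = np.concatenate([np.zeros_like(cum[..., :1]), cum], axis=-1)
    hi = np.concatenate([cum, total], axis=-1)
    return np.maximum(hi - lo, 0.0).transpose(1, 2, 0, 3)


def _predict_rce(spec, params, design, n_nodes):
    """Response-congruent evidence: winner density times loser CDF per rating bin."""
    s_id, strength, _, sigma = _condition_grid(params, spec, design)
    e_minus, e_plus, _ = rating_edges(spec, params)
    mu_m = 0.5 * (1.0 - s_id) * strength - params.theta_id
    mu_p = 0.5 * (1.0 + s_id) * strength + params.theta_id
    u, wq = _leggauss01(n_nodes)
    big = 1e30
    p = np.zeros((2, design.n_soa, 2, design.n_categories))
    for r, (edges, mu_win, mu_lose) in ((0, (e_minus, mu_m, mu_p)), (1, (e_plus, mu_p, mu_m))):
        bounds = np.concatenate([[-big], edges, [big]])
        qa = ndtr((bounds[:-1][None, None, :] - mu_win[..., None]) / sigma[..., None])
        qb = ndtr((bounds[1:][None, None, :] - mu_win[..., None]) / sigma[..., None])
        # nodes in probability space of the winning channel, per bin: (2, T, V, K)
        pr = np.clip(qa[..., None] + (qb - qa)[..., None] * u, _P_EPS, 1.0 - _P_EPS)
        x = mu_win[..., None, None] + sigma[..., None, None] * ndtri(pr)
        lose_cdf = ndtr((x - mu_lose[..., None, None]) / sigma[..., None, None])
        p[:, :, r, :] = (qb - qa) * np.einsum("k,stvk->stv", wq, lose_cdf)
    return p


def _log_odds_fn(s_noise: float, soa_set: np.ndarray):
    """H(x) = log sum_t exp((x*t - t^2/2) / s^2); strictly increasing in x."""
    t = np.asarray(soa_set, dtype=float)
    coef = t / s_noise**2
    const = -(t**2) / (2.0 * s_noise**2)

    def h(x):
        x = np.asarray(x, dtype=float)
        return logsumexp(x[..., None] * coef + const, axis=-1)

    return h, coef, const


def _predict_bayes2d(spec, params, design, n_nodes):
    soas = np.asarray(design.soa_levels_ms)
    s = params.s_noise
    h, coef, const = _log_odds_fn(s, soas)
    crit_logodds = logit(np.asarray(params.theta_post, dtype=float))
    u, wq = _leggauss01(n_nodes)
    n_cat = design.n_categories
    n_opt = 2 * n_cat
    z_nodes = ndtri(np.clip(u, _P_EPS, 1.0 - _P_EPS))
    s_id = np.array([-1.0, 1.0])[:, None]
    mu_m = 0.5 * (1.0 - s_id) * soas[None, :]  # (2, T)
    mu_p = 0.5 * (1.0 + s_id) * soas[None, :]
    d_minus = mu_m[..., None] + s * z_nodes  # (2, T, K)
    # H is strictly increasing, so posterior-band edges in delta_plus are found
    # by inverting H on a dense grid covering all reachable evidence values;
    # clamped extrapolation is safe because the conditional CDF saturates there.
    x_lo = min(0.0, float(soas.min())) - 12.0 * s
    x_hi = float(soas.max()) + 12.0 * s
    grid = np.linspace(x_lo, x_hi, 4001)
    h_grid = h(grid)
    targets = np.interp(d_minus, grid, h_grid)[..., None] + crit_logodds
    bounds = np.interp(targets, h_grid, grid)  # (2, T, K, n_opt - 1)
    cdf = ndtr((bounds - mu_p[..., None, None]) / s)
    lo = np.concatenate([np.zeros_like(cdf[..., :1]), cdf], axis=-1)
    hi = np.concatenate([cdf, np.ones_like(cdf[..., :1])], axis=-1)
    p_opt = np.einsum("k,stkj->stj", wq, hi - lo)  # (2, T, n_opt)
    p_opt = (1.0 - params.lam) * p_opt + params.lam / n_opt
    p = np.zeros((2, design.n_soa, 2, n_cat))
    # options ordered by increasing posterior: (-1, v=max..0) then (+1, v=0..max)
    p[:, :, 0, :] = p_opt[:, :, :n_cat][:, :, ::-1]
    p[:, :, 1, :] = p_opt[:, :, n_cat:]
    return p


def posterior_identity(delta_minus, delta_plus, s_noise: float, soa_set) -> np.ndarray:
    """P(S_id = +1 | delta_minus, delta_plus) under a flat prior over SOAs.

    Both identities and all SOAs in ``soa_set`` are marginalized with equal
    prior weight; computed through log-sum-exp for numerical safety.
    """
    if s_noise <= 0:
        raise ParameterError("s_noise must be positive")
    soa_set = np.asarray(soa_set, dtype=float)
    if soa_set.size == 0:
        raise ParameterError("soa_set must be nonempty")
    h, _, _ = _log_odds_fn(s_noise, soa_set)
    return expit(h(np.asarray(delta_plus, dtype=float)) - h(np.asarray(delta_minus, dtype=float)))


def predict_response_probabilities(
    spec: ModelSpec,
    params: ParameterSet,
    design: ExperimentDesign | None = None,
    n_nodes: int = 61,
    check: bool = True,
    validate: bool = True,
) -> ConditionProbabilityTable:
    """Joint P(R_id, R_v | S_id, SOA) for every condition of the design.

    Parameters
    ----------
    spec, params : model family/variance mode and its parameters.
    design : experiment layout (defaults to the 5-SOA masked-orientation design).
    n_nodes : quadrature nodes for the marginalization integrals.
    check : verify per-condition normalization to 1 +/- 1e-6.
    validate : check parameter invariants first (skippable inside optimizers
        whose reparameterization guarantees them).
    """
    design = design or ExperimentDesign()
    if validate:
        validate_parameters(spec, params, design)
    fam = spec.family
    if fam == "sdt":
        p = _predict_sdt(spec, params, design)
    elif fam == "two_channel":
        p = _predict_two_channel(spec, params, design)
    elif fam in ("noisy_sdt", "wev", "postdecisional", "cnd"):
        p = _predict_truncated_linear(spec, params, design, n_nodes)
    elif fam == "rce":
        p = _predict_rce(spec, params, design, n_nodes)
    elif fam == "bayes2d":
        p = _predict_bayes2d(spec, params, design, n_nodes)
    else:  # pragma: no cover
        raise ParameterError(f"unknown family '{fam}'")
    table = ConditionProbabilityTable(design, p)
    if check:
        table.check_normalization()
    return table


def probability_table_frame(table: ConditionProbabilityTable) -> pd.DataFrame:
    """Long-format export (stimulus, soa_ms, response, category, p)."""
    design = table.design
    rows = []
    for si, s in enumerate((-1, 1)):
        for ti, soa in enumerate(design.soa_levels_ms):
            for ri, r in enumerate((-1, 1)):
                for v in range(design.n_categories):
                    rows.append((s, soa, r, v, table.p[si, ti, ri, v]))
    return pd.DataFrame(rows, columns=["stimulus", "soa_ms", "response", "category", "p"])
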