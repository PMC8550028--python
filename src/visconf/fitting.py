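"""Per-participant maximum-likelihood fitting over discretized count tables.

The procedure mirrors standard practice for multinomial psychometric models:
a coarse grid over plausible starting values (seeded from the observed
hit/false-alarm rates and rating frequencies), Nelder-Mead simplex refinement
from the best grid points, and repeated restarts from each incumbent.

Optimization runs in an unconstrained internal parameterization: log for
positive parameters, logit for unit-interval parameters, base-plus-positive-
increments for the ordered criteria, and a stick-breaking map for the
2D Bayesian model's ordered posterior criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtri

from .data_model import CountTable, ExperimentDesign
from .models import (
    ModelSpec,
    ParameterSet,
    count_free_parameters,
    predict_response_probabilities,
    validate_parameters,
)

__all__ = [
    "FitSettings",
    "FitResult",
    "FitError",
    "negative_log_likelihood",
    "fit_model",
    "aicc",
    "bic",
    "pack_parameters",
    "unpack_parameters",
]

_P_FLOOR = 1e-10  # probability floor guarding structural zeros
_BAD = 1e12


class FitError(RuntimeError):
    """Raised when no optimizer start converges; carries the best incumbent."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class FitSettings:
    """Optimizer configuration.

    Defaults reproduce the procedure shape used throughout: five starting
    points from a coarse grid, simplex minimization, four restarts from each
    incumbent. ``n_nodes`` is the quadrature resolution used inside the
    likelihood during optimization.
    """

    n_starts: int = 5
    n_restarts: int = 4
    max_iter: int = 600
    xatol: float = 1e-4
    fatol: float = 1e-6
    n_nodes: int = 41
    seed: int = 0


#: Lighter settings for large simulation studies (recovery bootstraps).
RECOVERY_SETTINGS = FitSettings(n_starts=2, n_restarts=1, max_iter=150)


@dataclass
class FitResult:
    """Outcome of one model fit to one participant's counts."""

    spec: ModelSpec
    params: ParameterSet
    neg_log_likelihood: float
    aicc: float
    bic: float
    n_trials: int
    k_free: int
    converged: bool
    optimizer_trace: list = field(default_factory=list)
    n_function_evals: int = 0


def aicc(negll: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike criterion: 2*negll + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return 2.0 * negll + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def bic(negll: float, k: int, n: int) -> float:
    """Bayesian information criterion: 2*negll + k*ln(n)."""
    return 2.0 * negll + k * np.log(n)


def negative_log_likelihood(
    spec: ModelSpec,
    params: ParameterSet,
    counts: CountTable,
    n_nodes: int = 61,
) -> float:
    """-sum(n_cell * log p_cell) with probabilities floored at 1e-10."""
    validate_parameters(spec, params, counts.design)
    table = predict_response_probabilities(spec, params, counts.design, n_nodes=n_nodes, check=False)
    p = np.maximum(table.p, _P_FLOOR)
    return float(-(counts.counts * np.log(p)).sum())


# ---------------------------------------------------------------------------
# unconstrained parameterization


def _clip_exp(x):
    return np.exp(np.clip(x, -30.0, 8.0))


def _edges_up(vec4):
    """[base, log-increments x3] -> strictly increasing edges."""
    return vec4[0] + np.concatenate([[0.0], np.cumsum(_clip_exp(vec4[1:]))])


def _edges_up_inv(edges):
    d = np.diff(edges)
    return np.concatenate([[edges[0]], np.log(np.maximum(d, 1e-12))])


def _stick_up(z):
    """Unconstrained vector -> strictly increasing points in (0, 1).

    Normalized positive increments with one implicit final stick of unit
    weight; clipping keeps every increment large enough to survive float
    addition, so strict monotonicity holds for arbitrary inputs.
    """
    e = np.exp(np.clip(z, -15.0, 15.0))
    return np.cumsum(e) / (e.sum() + 1.0)


def _stick_up_inv(c):
    c = np.asarray(c, dtype=float)
    last = max(1.0 - c[-1], 1e-12)
    d = np.diff(np.concatenate([[0.0], c]))
    return np.log(np.maximum(d, 1e-15) / last)


def _layout(spec: ModelSpec, design: ExperimentDesign):
    """Ordered list of (field, kind, size) blocks in the packed vector."""
    n_soa, n_cat = design.n_soa, design.n_categories
    if spec.family == "bayes2d":
        blocks = [
            ("s_noise", "log", 1),
            ("lam", "logit", 1),
            ("theta_post", "stick", 2 * n_cat - 1),
        ]
    else:
        blocks = [
            ("s_s", "log_vec", n_soa),
            ("theta_id", "raw", 1),
            ("theta_v_plus", "edges_up", n_cat - 1),
            (
                "theta_v_minus",
                "edges_up" if spec.family == "rce" else "edges_down",
                n_cat - 1,
            ),
        ]
        if spec.family in ("noisy_sdt", "wev", "cnd"):
            blocks.append(("sigma_v", "log", 1))
        if spec.family == "wev":
            blocks.append(("w", "logit", 1))
        if spec.family == "two_channel":
            blocks.append(("a", "log", 1))
        if spec.family == "postdecisional":
            blocks.append(("b", "log", 1))
        if spec.family == "cnd":
            blocks.append(("rho", "logit_vec", n_soa))
    if spec.variance_mode == "identity_dependent":
        blocks.append(("r_id", "log", 1))
    if spec.variance_mode == "soa_dependent":
        blocks.append(("k", "log", 1))
    return blocks


def pack_parameters(spec: ModelSpec, params: ParameterSet, design: ExperimentDesign) -> np.ndarray:
    """Map a valid ParameterSet to the unconstrained optimizer vector."""
    out = []
    for name, kind, size in _layout(spec, design):
        v = getattr(params, name)
        if kind == "raw":
            out.append([float(v)])
        elif kind == "log":
            out.append([np.log(max(float(v), 1e-12))])
        elif kind == "logit":
            out.append([logit(np.clip(float(v), 1e-9, 1 - 1e-9))])
        elif kind == "log_vec":
            out.append(np.log(np.maximum(np.asarray(v, float), 1e-12)))
        elif kind == "logit_vec":
            out.append(logit(np.clip(np.asarray(v, float), 1e-9, 1 - 1e-9)))
        elif kind == "edges_up":
            out.append(_edges_up_inv(np.asarray(v, float)))
        elif kind == "edges_down":
            # decreasing criteria are packed as increasing edges on the mirrored axis
            out.append(_edges_up_inv(-np.asarray(v, float)))
        elif kind == "stick":
            out.append(_stick_up_inv(np.asarray(v, float)))
        else:  # pragma: no cover
            raise ValueError(kind)
    return np.concatenate(out)


def unpack_parameters(spec: ModelSpec, x: np.ndarray, design: ExperimentDesign) -> ParameterSet:
    """Inverse of :func:`pack_parameters`; always yields a valid ParameterSet."""
    params = ParameterSet()
    i = 0
    for name, kind, size in _layout(spec, design):
        chunk = np.asarray(x[i : i + size], dtype=float)
        i += size
        if kind == "raw":
            val = float(chunk[0])
        elif kind == "log":
            val = float(_clip_exp(chunk[0]))
        elif kind == "logit":
            val = float(expit(chunk[0]))
        elif kind == "log_vec":
            val = _clip_exp(chunk)
        elif kind == "logit_vec":
            val = expit(chunk)
        elif kind == "edges_up":
            val = _edges_up(chunk)
        elif kind == "edges_down":
            val = -_edges_up(chunk)
        elif kind == "stick":
            val = _stick_up(chunk)
        else:  # pragma: no cover
            raise ValueError(kind)
        setattr(params, name, val)
    params.__post_init__()
    return params


# ---------------------------------------------------------------------------
# grid starts


def _observed_summaries(counts: CountTable):
    c = counts.counts.astype(float)
    n_cond = c.sum(axis=(2, 3)) + 1.0  # (2, T), continuity
    p_plus = (c[:, :, 1, :].sum(axis=-1) + 0.5) / n_cond
    z = ndtri(np.clip(p_plus, 1e-3, 1 - 1e-3))
    dprime = np.clip(z[1] - z[0], 0.05, 5.0)  # per SOA
    theta0 = float(np.mean(-0.5 * (z[1] + z[0])))
    # interior cumulative rating frequencies per response, on the oriented axis
    qs = []
    for r in (0, 1):
        # categories are ascending along each response's oriented report axis,
        # so cumulative category frequencies estimate the CDF at the edges
        f = c[:, :, r, :].sum(axis=(0, 1)) + 0.5
        q = np.cumsum(f)[:-1] / f.sum()
        q = np.clip(q, 0.02, 0.98)
        q = np.maximum.accumulate(q + np.arange(len(q)) * 1e-6)
        qs.append(np.clip(q, 0.01, 0.995))
    return dprime, theta0, qs


def _criteria_from_quantiles(q, center, spread):
    e = center + spread * ndtri(q)
    return e + np.arange(len(e)) * 1e-4  # guarantee strict increase


def _grid_candidates(spec: ModelSpec, counts: CountTable, design: ExperimentDesign):
    dprime, theta0, (q_minus, q_plus) = _observed_summaries(counts)
    fam = spec.family
    cands = []
    if fam == "bayes2d":
        c = counts.counts.astype(float)
        n_cat = design.n_categories
        # empirical option frequencies along the posterior-ordered axis
        f_minus = c[:, :, 0, :].sum(axis=(0, 1))[::-1]
        f_plus = c[:, :, 1, :].sum(axis=(0, 1))
        f = np.concatenate([f_minus, f_plus]) + 0.5
        cum = np.cumsum(f)[:-1] / f.sum()
        cum = np.maximum.accumulate(np.clip(cum, 5e-3, 1 - 5e-3) + np.arange(2 * n_cat - 1) * 1e-6)
        theta_post = np.clip(cum, 1e-3, 1 - 1e-3)
        for s_noise in (15.0, 30.0, 60.0, 120.0):
            for lam in (0.01, 0.05):
                cands.append(ParameterSet(s_noise=s_noise, lam=lam, theta_post=theta_post.copy()))
        return cands

    center_plus = 0.5 * float(np.mean(dprime))
    if fam == "rce":
        center_plus = 0.5 * float(np.mean(dprime)) + 0.5
    for scale in (0.6, 1.0, 1.4):
        for spread in (0.8, 1.5):
            for dth in (-0.3, 0.0, 0.3):
                e_plus = _criteria_from_quantiles(q_plus, center_plus, spread)
                if fam == "rce":
                    tvm = _criteria_from_quantiles(q_minus, center_plus, spread)
                else:
                    # quantiles live on the mirrored (-delta_v) axis; map back
                    tvm = -_criteria_from_quantiles(q_minus, center_plus, spread)
                base = dict(
                    s_s=np.clip(dprime * scale, 1e-3, 8.0),
                    theta_id=theta0 + dth,
                    theta_v_plus=e_plus,
                    theta_v_minus=tvm,
                )
                if fam in ("sdt", "rce"):
                    cands.append(ParameterSet(**base))
                elif fam == "noisy_sdt":
                    for sv in (0.5, 1.0, 2.0):
                        cands.append(ParameterSet(**base, sigma_v=sv))
                elif fam == "wev":
                    for sv in (0.5, 1.0, 2.0):
                        for w in (0.25, 0.5, 0.75):
                            cands.append(ParameterSet(**base, sigma_v=sv, w=w))
                elif fam == "two_channel":
                    for a in (0.5, 1.0, 2.0):
                        cands.append(ParameterSet(**base, a=a))
                elif fam == "postdecisional":
                    for b in (0.5, 1.0, 2.0):
                        cands.append(ParameterSet(**base, b=b))
                elif fam == "cnd":
                    for sv in (0.5, 1.0, 2.0):
                        for rho in (0.3, 0.7):
                            cands.append(
                                ParameterSet(**base, sigma_v=sv, rho=np.full(design.n_soa, rho))
                            )
    return cands


def _finalize_candidates(spec, cands, design):
    out = []
    for ps in cands:
        if spec.variance_mode == "identity_dependent":
            ps.r_id = 1.0
        if spec.variance_mode == "soa_dependent":
            ps.k = 0.1
        out.append(ps)
    return out


def fit_model(
    spec: ModelSpec,
    counts: CountTable,
    settings: FitSettings | None = None,
    design: ExperimentDesign | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one family to one participant's counts.

    Coarse grid -> best ``n_starts`` grid points seed Nelder-Mead runs ->
    each run restarted ``n_restarts`` times from its incumbent -> best
    overall returned. Deterministic for fixed data and settings.
    """
    settings = settings or FitSettings()
    design = design or counts.design
    if counts.n_trials == 0:
        raise FitError("cannot fit an empty count table")
    n_nodes = settings.n_nodes
    cn = counts.counts

    def objective(x):
        try:
            params = unpack_parameters(spec, x, design)
            table = predict_response_probabilities(
                spec, params, design, n_nodes=n_nodes, check=False, validate=False
            )
        except (ValueError, FloatingPointError):
            return _BAD
        p = np.maximum(table.p, _P_FLOOR)
        val = -(cn * np.log(p)).sum()
        return val if np.isfinite(val) else _BAD

    candidates = _finalize_candidates(spec, _grid_candidates(spec, counts, design), design)
    xs = [pack_parameters(spec, ps, design) for ps in candidates]
    grid_vals = np.array([objective(x) for x in xs])
    order = np.argsort(grid_vals)
    best_grid = float(grid_vals[order[0]])

    best_x, best_val = xs[order[0]], best_grid
    trace = [(0, best_grid)]
    n_fev = len(xs)
    converged = False
    for rank in order[: settings.n_starts]:
        x = xs[rank].copy()
        for _ in range(1 + settings.n_restarts):
            res = minimize(
                objective,
                x,
                method="Nelder-Mead",
                options=dict(
                    maxiter=settings.max_iter,
                    xatol=settings.xatol,
                    fatol=settings.fatol,
                    adaptive=True,
                ),
            )
            n_fev += res.nfev
            x = res.x
            if res.fun < best_val:
                best_val, best_x = float(res.fun), res.x.copy()
            converged = converged or bool(res.success)
            trace.append((n_fev, float(res.fun)))
    if best_val >= _BAD:
        raise FitError("all optimizer starts failed", best=None)

    params = unpack_parameters(spec, best_x, design)
    # final likelihood at full quadrature resolution
    negll = negative_log_likelihood(spec, params, counts, n_nodes=61)
    k = count_free_parameters(spec, design)
    n = counts.n_trials
    return FitResult(
        spec=spec,
        params=params,
        neg_log_likelihood=float(negll),
        aicc=aicc(negll, k, n),
        bic=bic(negll, k, n),
        n_trials=n,
        k_free=k,
        converged=converged,
        optimizer_trace=trace,
        n_function_evals=n_fev,
    )
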