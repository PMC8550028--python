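"""Model families, parameter containers, and structural bookkeeping.

All families share the coding conventions: stimulus identity S_id in {-1, +1},
identification response R_id in {-1, +1}, rating category R_v in
{0, ..., n_categories - 1}. Stimulus strength is a per-SOA sensitivity
parameter S_s >= 0; with unit identification noise it plays the role of d'.

Rating-criteria geometry
------------------------
A separate criteria set applies per identification response. For R_id = +1 the
four criteria ``theta_v_plus`` are strictly increasing on the report variable
delta_v; larger delta_v means a higher category. For R_id = -1 the mapping is
mirrored: ``theta_v_minus`` is strictly decreasing and *more negative* delta_v
means a higher category. The response-congruent-evidence family is the
exception: its report variable is the winning evidence channel, which is large
whenever its response wins, so both criteria sets are strictly increasing on
the winning channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..data_model import ExperimentDesign

__all__ = [
    "FAMILIES",
    "VARIANCE_MODES",
    "ModelSpec",
    "ParameterSet",
    "ParameterError",
    "count_free_parameters",
    "sigma_id_of",
    "validate_parameters",
    "rating_edges",
    "mu_id",
]

FAMILIES = (
    "sdt",
    "noisy_sdt",
    "wev",
    "two_channel",
    "postdecisional",
    "cnd",
    "rce",
    "bayes2d",
)

VARIANCE_MODES = ("constant", "identity_dependent", "soa_dependent")


class ParameterError(ValueError):
    """Raised when a parameter set violates its family's constraints."""


@dataclass(frozen=True)
class ModelSpec:
    """A model family paired with a variance assumption.

    ``variance_mode`` controls the standard deviation of the identification
    decision variable: ``constant`` fixes it at 1; ``identity_dependent``
    scales it as r_id ** S_id; ``soa_dependent`` as sqrt(1 + k * S_s**2).
    The 2D Bayesian family carries its own noise parameter and therefore only
    admits the constant mode.
    """

    family: str
    variance_mode: str = "constant"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family '{self.family}'")
        if self.variance_mode not in VARIANCE_MODES:
            raise ParameterError(f"unknown variance mode '{self.variance_mode}'")
        if self.family == "bayes2d" and self.variance_mode != "constant":
            raise ParameterError("bayes2d admits only constant variance")

    def label(self) -> str:
        return f"{self.family}/{self.variance_mode}"


@dataclass
class ParameterSet:
    """Named parameters; only the fields relevant to a family are active.

    Attributes
    ----------
    s_s : per-SOA sensitivity (distance between the identity distributions).
    theta_id : identification criterion (bias parameter for rce/bayes2d).
    theta_v_minus, theta_v_plus : rating criteria for R_id = -1 / +1.
    sigma_v : report noise (noisy SDT, WEV, constant noise and decay).
    w : weight on identity-irrelevant stimulus-strength evidence (WEV).
    a : signal fraction of the second channel (two-channel).
    b : postdecisional accumulation relative to first-stage evidence.
    rho : per-SOA multiplicative signal decay in (0, 1) (cnd).
    s_noise : perceptual noise of the 2D Bayesian model (on the SOA-ms axis).
    lam : lapse rate of the 2D Bayesian model.
    theta_post : 9 increasing posterior criteria in (0, 1) (2D Bayesian).
    r_id : identity-dependent variance ratio (variance mode parameter).
    k : slope of the SOA-dependent variance increase.
    """

    s_s: np.ndarray | None = None
    theta_id: float | None = None
    theta_v_minus: np.ndarray | None = None
    theta_v_plus: np.ndarray | None = None
    sigma_v: float | None = None
    w: float | None = None
    a: float | None = None
    b: float | None = None
    rho: np.ndarray | None = None
    s_noise: float | None = None
    lam: float | None = None
    theta_post: np.ndarray | None = None
    r_id: float | None = None
    k: float | None = None

    def __post_init__(self):
        for name in ("s_s", "theta_v_minus", "theta_v_plus", "rho", "theta_post"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))

    def copy(self) -> "ParameterSet":
        return replace(self)

    @property
    def mean_strength(self) -> float:
        """Mean of S_s across SOA conditions (the WEV reference strength)."""
        return float(np.mean(self.s_s))


def mu_id(s_id: int, strength: float) -> float:
    """Mean of the identification decision variable: S_id * S_s / 2."""
    return 0.5 * s_id * strength


def sigma_id_of(variance_mode: str, params: ParameterSet, s_id, strength):
    """Standard deviation of the identification decision variable.

    constant -> 1; identity_dependent -> r_id ** S_id;
    soa_dependent -> sqrt(1 + k * S_s**2).
    """
    if variance_mode == "constant":
        return np.ones_like(np.asarray(s_id, dtype=float) * np.asarray(strength, dtype=float))
    if variance_mode == "identity_dependent":
        if params.r_id is None or params.r_id <= 0:
            raise ParameterError("identity_dependent mode requires r_id > 0")
        return np.asarray(params.r_id, dtype=float) ** np.asarray(s_id, dtype=float) * np.ones_like(
            np.asarray(strength, dtype=float)
        )
    if variance_mode == "soa_dependent":
        if params.k is None or params.k < 0:
            raise ParameterError("soa_dependent mode requires k >= 0")
        return np.sqrt(1.0 + params.k * np.asarray(strength, dtype=float) ** 2) * np.ones_like(
            np.asarray(s_id, dtype=float)
        )
    raise ParameterError(f"unknown variance mode '{variance_mode}'")


def _require(cond: bool, msg: str):
    if not cond:
        raise ParameterError(msg)


def validate_parameters(spec: ModelSpec, params: ParameterSet, design: ExperimentDesign):
    """Check all structural constraints of a parameter set for a family.

    Raises :class:`ParameterError` on the first violation.
    """
    n_soa, n_cat = design.n_soa, design.n_categories
    fam = spec.family
    if fam != "bayes2d":
        _require(params.s_s is not None and len(params.s_s) == n_soa, "s_s must have one entry per SOA")
        _require(bool(np.all(params.s_s >= 0)), "s_s must be nonnegative")
        _require(params.theta_id is not None and np.isfinite(params.theta_id), "theta_id required")
        for name in ("theta_v_minus", "theta_v_plus"):
            v = getattr(params, name)
            _require(v is not None and len(v) == n_cat - 1, f"{name} must have {n_cat - 1} entries")
            _require(bool(np.all(np.isfinite(v))), f"{name} must be finite")
        _require(bool(np.all(np.diff(params.theta_v_plus) > 0)), "theta_v_plus must be strictly increasing")
        if fam == "rce":
            _require(
                bool(np.all(np.diff(params.theta_v_minus) > 0)),
                "rce theta_v_minus must be strictly increasing on the winning channel",
            )
        else:
            _require(bool(np.all(np.diff(params.theta_v_minus) < 0)), "theta_v_minus must be strictly decreasing")
    if fam in ("noisy_sdt", "wev", "cnd"):
        _require(params.sigma_v is not None and params.sigma_v > 0, "sigma_v must be positive")
    if fam == "wev":
        _require(params.w is not None and 0.0 <= params.w <= 1.0, "w must lie in [0, 1]")
    if fam == "two_channel":
        _require(params.a is not None and params.a >= 0, "a must be nonnegative")
    if fam == "postdecisional":
        _require(params.b is not None and params.b > 0, "b must be positive")
    if fam == "cnd":
        _require(params.rho is not None and len(params.rho) == n_soa, "rho must have one entry per SOA")
        _require(bool(np.all((params.rho > 0) & (params.rho <= 1))), "rho must lie in (0, 1]")
    if fam == "bayes2d":
        _require(params.s_noise is not None and params.s_noise > 0, "s_noise must be positive")
        _require(params.lam is not None and 0.0 <= params.lam <= 1.0, "lambda must lie in [0, 1]")
        tp = params.theta_post
        _require(tp is not None and len(tp) == 2 * n_cat - 1, f"theta_post must have {2 * n_cat - 1} entries")
        _require(bool(np.all((tp > 0) & (tp < 1))), "theta_post must lie in (0, 1)")
        _require(bool(np.all(np.diff(tp) > 0)), "theta_post must be strictly increasing")
    if spec.variance_mode == "identity_dependent":
        _require(params.r_id is not None and params.r_id > 0, "r_id must be positive")
    if spec.variance_mode == "soa_dependent":
        _require(params.k is not None and params.k >= 0, "k must be nonnegative")


def count_free_parameters(spec: ModelSpec, design: ExperimentDesign | None = None) -> int:
    """Number of free parameters of a family under a design.

    With 5 SOAs and 5 rating categories under constant variance this yields
    14 (sdt, rce), 15 (noisy_sdt, two_channel, postdecisional), 16 (wev),
    20 (cnd), and 11 (bayes2d); non-constant variance modes add one.
    """
    design = design or ExperimentDesign()
    n_soa, n_cat = design.n_soa, design.n_categories
    n_criteria = 2 * (n_cat - 1)
    base = n_soa + 1 + n_criteria  # s_s per SOA, theta_id, two criteria sets
    extra = {
        "sdt": 0,
        "rce": 0,
        "noisy_sdt": 1,  # sigma_v
        "two_channel": 1,  # a
        "postdecisional": 1,  # b
        "wev": 2,  # w, sigma_v
        "cnd": n_soa + 1,  # rho per SOA, sigma_v
    }
    if spec.family == "bayes2d":
        k = 2 + (2 * n_cat - 1)  # s_noise, lambda, posterior criteria
    else:
        k = base + extra[spec.family]
    if spec.variance_mode != "constant":
        k += 1
    return k


def rating_edges(spec: ModelSpec, params: ParameterSet):
    """Increasing bin edges for each response on its oriented report axis.

    Returns ``(edges_minus, edges_plus, orient_minus)``. For R_id = +1 the
    report variable is delta_v itself. For R_id = -1 the mirrored convention
    places the report on -delta_v (``orient_minus = -1``); for rce the winning
    channel is used directly (``orient_minus = +1``).
    """
    e_plus = np.asarray(params.theta_v_plus, dtype=float)
    m = np.asarray(params.theta_v_minus, dtype=float)
    if spec.family == "rce":
        return m, e_plus, 1.0
    return -m, e_plus, -1.0
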