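"""Synthetic cohorts with the statistical structure of the masked-orientation experiments.

No raw data are deposited with the studies this package models, so complete
synthetic experiments stand in for them: per participant, a parameter set is
drawn from documented ranges, categorical trials are simulated from the
generative model, and a continuous rating is emitted uniformly within the
chosen category's partition of the [0, 1] scale (so that discretization
recovers the generating category exactly).

Default parameter ranges are chosen to emulate the masked-orientation
experiments: identification near chance at the 8.3 ms SOA, near ceiling at
133.3 ms, and ratings populating all five categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import EXP1_DESIGN, EXP2_DESIGN, ExperimentDesign
from .models import ModelSpec, ParameterSet, validate_parameters
from .models.families import rating_edges
from .models.simulate import simulate_trials

__all__ = [
    "CohortConfig",
    "sample_parameters",
    "generate_cohort",
    "generate_joint",
    "DEFAULT_SENSITIVITY_PROFILE",
]

#: Increasing per-SOA sensitivity profile (chance at 8.3 ms, ceiling at 133.3 ms).
DEFAULT_SENSITIVITY_PROFILE = np.array([0.05, 0.6, 1.6, 2.6, 3.8])


@dataclass
class CohortConfig:
    """Configuration of a synthetic experiment.

    ``preset`` selects the trial arithmetic: 'exp1' (5 SOAs x 110 trials),
    'exp2' (5 SOAs x 81 trials) or 'custom' (use ``design``).
    """

    preset: str = "exp1"
    n_participants: int = 31
    spec: ModelSpec = field(default_factory=lambda: ModelSpec("wev"))
    seed: int = 0
    design: ExperimentDesign | None = None
    judgment_type: str = "visibility"

    def resolve_design(self) -> ExperimentDesign:
        if self.preset == "exp1":
            return EXP1_DESIGN
        if self.preset == "exp2":
            return EXP2_DESIGN
        if self.preset == "custom":
            if self.design is None:
                raise ValueError("custom preset requires a design")
            return self.design
        raise ValueError(f"unknown preset '{self.preset}'")


def _draw_criteria(rng, base_range, step_range, n_edges):
    base = rng.uniform(*base_range)
    steps = rng.uniform(*step_range, size=n_edges - 1)
    return base + np.concatenate([[0.0], np.cumsum(steps)])


def sample_parameters(
    spec: ModelSpec | str,
    seed: int | np.random.Generator = 0,
    design: ExperimentDesign | None = None,
    ranges: dict | None = None,
) -> ParameterSet:
    """Draw a parameter set uniformly within documented default ranges.

    ``ranges`` may override any of: ``s_s_jitter``, ``theta_id``, ``sigma_v``,
    ``w``, ``a``, ``b``, ``rho``, ``s_noise``, ``lam`` (each a (lo, hi) pair),
    ``s_s_profile`` (array), ``criteria_base`` and ``criteria_step``.
    Criteria are generated ordered by construction, so every draw satisfies
    the parameter invariants.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    design = design or ExperimentDesign()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = {
        "s_s_profile": DEFAULT_SENSITIVITY_PROFILE[: design.n_soa],
        "s_s_jitter": (-0.25, 0.25),
        "theta_id": (-0.2, 0.2),
        "sigma_v": (0.5, 1.5),
        "w": (0.2, 0.7),
        "a": (0.5, 1.5),
        "b": (0.5, 2.0),
        "rho": (0.3, 0.9),
        "s_noise": (20.0, 60.0),
        "lam": (0.01, 0.05),
        "criteria_base": (-0.6, -0.1),
        "criteria_step": (0.35, 0.75),
    }
    if ranges:
        r.update(ranges)
    n_edges = design.n_categories - 1

    if spec.family == "bayes2d":
        n_crit = 2 * design.n_categories - 1
        center = rng.uniform(-0.4, 0.4)
        steps = rng.uniform(0.5, 1.1, size=n_crit - 1)
        logodds = center + np.concatenate([[0.0], np.cumsum(steps)])
        logodds -= logodds[(n_crit - 1) // 2]
        params = ParameterSet(
            s_noise=rng.uniform(*r["s_noise"]),
            lam=rng.uniform(*r["lam"]),
            theta_post=1.0 / (1.0 + np.exp(-logodds)),
        )
        validate_parameters(spec, params, design)
        return params

    profile = np.asarray(r["s_s_profile"], dtype=float)
    s_s = np.clip(profile + rng.uniform(*r["s_s_jitter"], size=design.n_soa), 0.0, None)
    if spec.family == "rce":
        base = rng.uniform(0.2, 0.8)
        plus = base + np.concatenate([[0.0], np.cumsum(rng.uniform(0.45, 0.85, size=n_edges - 1))])
        base2 = rng.uniform(0.2, 0.8)
        minus = base2 + np.concatenate([[0.0], np.cumsum(rng.uniform(0.45, 0.85, size=n_edges - 1))])
    else:
        plus = _draw_criteria(rng, r["criteria_base"], r["criteria_step"], n_edges)
        minus = -_draw_criteria(rng, r["criteria_base"], r["criteria_step"], n_edges)
    params = ParameterSet(
        s_s=s_s,
        theta_id=rng.uniform(*r["theta_id"]),
        theta_v_plus=plus,
        theta_v_minus=minus,
    )
    if spec.family in ("noisy_sdt", "wev", "cnd"):
        params.sigma_v = rng.uniform(*r["sigma_v"])
    if spec.family == "wev":
        params.w = rng.uniform(*r["w"])
    if spec.family == "two_channel":
        params.a = rng.uniform(*r["a"])
    if spec.family == "postdecisional":
        params.b = rng.uniform(*r["b"])
    if spec.family == "cnd":
        params.rho = rng.uniform(*r["rho"], size=design.n_soa)
    if spec.variance_mode == "identity_dependent":
        params.r_id = rng.uniform(0.8, 1.25)
    if spec.variance_mode == "soa_dependent":
        params.k = rng.uniform(0.0, 0.2)
    validate_parameters(spec, params, design)
    return params


def _continuous_from_categories(categories, n_categories, rng):
    """Uniform draw within each category's partition; discretization inverts it."""
    u = rng.uniform(0.0, 1.0, size=len(categories))
    width = 1.0 / n_categories
    rating = (np.asarray(categories) + np.clip(u, 1e-9, 1 - 1e-9)) * width
    return np.clip(rating, 0.0, 1.0 - 1e-12)


def generate_cohort(config: CohortConfig):
    """Generate a full synthetic experiment.

    Returns ``(trials, parameter_sets)``: a trial DataFrame with continuous
    ratings for all participants, and the per-participant generating
    parameters. Fully reproducible under ``config.seed``.
    """
    design = config.resolve_design()
    root = np.random.SeedSequence(config.seed)
    frames, param_sets = [], {}
    for i, child in enumerate(root.spawn(config.n_participants)):
        rng = np.random.default_rng(child)
        pid = f"p{i + 1:03d}"
        params = sample_parameters(config.spec, rng, design)
        trials = simulate_trials(
            config.spec, params, design, rng, participant_id=pid, judgment_type=config.judgment_type
        )
        trials["rating"] = _continuous_from_categories(
            trials["category"].to_numpy(), design.n_categories, rng
        )
        frames.append(trials)
        param_sets[pid] = params
    return pd.concat(frames, ignore_index=True), param_sets


def generate_joint(
    params: ParameterSet,
    w_vis: float,
    w_conf: float,
    design: ExperimentDesign | None = None,
    n_trials_per_condition: int | None = None,
    noise_mode: str = "shared",
    seed: int | np.random.Generator = 0,
    theta_v_plus_conf=None,
    theta_v_minus_conf=None,
) -> pd.DataFrame:
    """Simulate visibility and confidence reports for the same trials.

    Both reports share each trial's identification evidence draw; their
    report variables use their own weights (``w_vis``, ``w_conf``) and,
    optionally, separate criteria sets. Under ``noise_mode='shared'`` the
    same report-noise disturbance is reused for both judgments; under
    ``'independent'`` it is redrawn.
    """
    if noise_mode not in ("shared", "independent"):
        raise ValueError("noise_mode must be 'shared' or 'independent'")
    design = design or ExperimentDesign()
    spec = ModelSpec("wev")
    validate_parameters(spec, params, design)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e_minus, e_plus, orient_minus = rating_edges(spec, params)
    if theta_v_plus_conf is None:
        e_plus_c, e_minus_c = e_plus, e_minus
    else:
        e_plus_c = np.asarray(theta_v_plus_conf, dtype=float)
        e_minus_c = -np.asarray(theta_v_minus_conf, dtype=float)
    rows = []
    n_minus, n_plus = design.trials_per_identity()
    for ti, soa in enumerate(design.soa_levels_ms):
        strength = float(params.s_s[ti])
        for s_id, n_default in ((-1, n_minus), (1, n_plus)):
            n = n_trials_per_condition or n_default
            delta_id = rng.normal(0.5 * s_id * strength, 1.0, size=n)
            resp = np.where(delta_id < params.theta_id, -1, 1)
            z_vis = rng.standard_normal(n)
            z_conf = z_vis if noise_mode == "shared" else rng.standard_normal(n)
            rel = strength - params.mean_strength
            dv_vis = (1 - w_vis) * delta_id + w_vis * resp * rel + params.sigma_v * z_vis
            dv_conf = (1 - w_conf) * delta_id + w_conf * resp * rel + params.sigma_v * z_conf
            cat_vis = np.where(
                resp > 0,
                np.searchsorted(e_plus, dv_vis, side="right"),
                np.searchsorted(e_minus, orient_minus * dv_vis, side="right"),
            )
            cat_conf = np.where(
                resp > 0,
                np.searchsorted(e_plus_c, dv_conf, side="right"),
                np.searchsorted(e_minus_c, orient_minus * dv_conf, side="right"),
            )
            rows.append(
                pd.DataFrame(
                    {
                        "soa_ms": soa,
                        "stimulus": s_id,
                        "response": resp,
                        "category_visibility": cat_vis,
                        "category_confidence": cat_conf,
                    }
                )
            )
    trials = pd.concat(rows, ignore_index=True)
    trials["visibility"] = _continuous_from_categories(
        trials["category_visibility"].to_numpy(), design.n_categories, rng
    )
    trials["confidence"] = _continuous_from_categories(
        trials["category_confidence"].to_numpy(), design.n_categories, rng
    )
    return trials
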