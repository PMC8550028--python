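"""Observed-versus-predicted descriptive statistics.

Gamma correlations between stimulus strength (SOA rank) and rating category,
split by identification accuracy, are the key qualitative signature the model
comparison turns on: models whose report variable carries identity-irrelevant
stimulus-strength information predict a positive strength-rating association
even on incorrect trials. The Goodman–Kruskal gamma is used because both
variables are ordinal with heavy ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExperimentDesign
from .models import ModelSpec, ParameterSet, predict_response_probabilities

__all__ = [
    "GammaResult",
    "goodman_kruskal_gamma",
    "gamma_from_table",
    "gamma_by_accuracy",
    "predicted_gamma",
    "Contingency20",
    "contingency_20",
]


@dataclass
class GammaResult:
    """Gamma correlations within correct and incorrect trials.

    Either value is NaN when its subset has no untied pair.
    """

    gamma_correct: float
    gamma_incorrect: float
    n_pairs_correct: float
    n_pairs_incorrect: float


def gamma_from_table(weights: np.ndarray) -> tuple[float, float]:
    """Gamma and untied-pair count from a (possibly fractional) x-by-y table.

    Concordant/discordant pair counts use products of cell weights, which is
    exact for expected frequencies; within-cell pairs are ties and excluded.
    Returns ``(gamma, C + D)`` with gamma NaN when no untied pair exists.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2:
        raise ValueError("weights must be a 2-D table")
    # cumulative mass strictly below/above in both orderings
    lower = np.zeros_like(w)
    lower[1:, 1:] = w.cumsum(axis=0).cumsum(axis=1)[:-1, :-1]
    upper = np.zeros_like(w)
    upper[:-1, :-1] = w[::-1, ::-1].cumsum(axis=0).cumsum(axis=1)[::-1, ::-1][1:, 1:]
    concordant = float((w * lower).sum())
    discordant_tab = np.zeros_like(w)
    discordant_tab[1:, :-1] = w[:, ::-1].cumsum(axis=0).cumsum(axis=1)[:, ::-1][:-1, 1:]
    discordant = float((w * discordant_tab).sum())
    total = concordant + discordant
    if total <= 0:
        return float("nan"), 0.0
    return (concordant - discordant) / total, total


def goodman_kruskal_gamma(x, y) -> float:
    """Goodman–Kruskal gamma: (C - D) / (C + D) over untied pairs.

    ``x`` and ``y`` are equal-length ordinal sequences; ties on either
    variable are excluded. Returns NaN when every pair is tied.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    table = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(table, (xi, yi), 1.0)
    gamma, _ = gamma_from_table(table)
    return gamma


def gamma_by_accuracy(trials: pd.DataFrame, design: ExperimentDesign | None = None) -> GammaResult:
    """Gamma between SOA rank and rating category, split by accuracy.

    Trials must carry ``soa_ms``, ``stimulus``, ``response`` and ``category``.
    """
    design = design or ExperimentDesign()
    t = design.soa_index(trials["soa_ms"].to_numpy())
    v = trials["category"].to_numpy()
    correct = trials["response"].to_numpy() == trials["stimulus"].to_numpy()
    out = {}
    for name, mask in (("correct", correct), ("incorrect", ~correct)):
        if mask.sum() < 2:
            out[name] = (float("nan"), 0.0)
            continue
        table = np.zeros((design.n_soa, design.n_categories))
        np.add.at(table, (t[mask], v[mask]), 1.0)
        out[name] = gamma_from_table(table)
    return GammaResult(
        gamma_correct=out["correct"][0],
        gamma_incorrect=out["incorrect"][0],
        n_pairs_correct=out["correct"][1],
        n_pairs_incorrect=out["incorrect"][1],
    )


def predicted_gamma(
    spec: ModelSpec, params: ParameterSet, design: ExperimentDesign | None = None
) -> GammaResult:
    """Model-implied gamma between SOA and rating, from expected frequencies.

    Expected counts per (SOA, category, accuracy) cell are assembled from the
    exact condition probability table, weighting conditions by their designed
    trial counts; gamma is then computed on the fractional tables.
    """
    design = design or ExperimentDesign()
    table = predict_response_probabilities(spec, params, design)
    n_minus, n_plus = design.trials_per_identity()
    n_cond = np.array([n_minus, n_plus], dtype=float)  # per (identity, SOA)
    w_corr = np.zeros((design.n_soa, design.n_categories))
    w_inc = np.zeros((design.n_soa, design.n_categories))
    for si in range(2):
        w_corr += n_cond[si] * table.p[si, :, si, :]  # response index == stimulus index
        w_inc += n_cond[si] * table.p[si, :, 1 - si, :]
    g_c, n_c = gamma_from_table(w_corr)
    g_i, n_i = gamma_from_table(w_inc)
    return GammaResult(g_c, g_i, n_c, n_i)


@dataclass
class Contingency20:
    """Dissociation rates between two graded reports at the 20% threshold.

    ``p_vis_given_lowconf``: probability of visibility above 0.2 on trials
    with confidence below 0.2 (and the converse), averaged per participant
    and then across participants. Ratings exactly at the threshold count as
    "not below".
    """

    p_vis_given_lowconf: float
    p_conf_given_lowvis: float
    n_participants: int
    n_excluded_vis: int
    n_excluded_conf: int


def contingency_20(trials: pd.DataFrame, threshold: float = 0.2) -> Contingency20:
    """Mutual dissociation rates of visibility and confidence reports.

    Trials need continuous ``visibility`` and ``confidence`` columns in
    [0, 1]; a ``participant`` column is optional (a single participant is
    assumed otherwise). Participants with an empty conditioning set are
    excluded from the corresponding mean.
    """
    df = trials.copy()
    if "participant" not in df.columns:
        df["participant"] = "all"
    vis_rates, conf_rates = [], []
    n_ex_vis = n_ex_conf = 0
    for _, g in df.groupby("participant"):
        vis = g["visibility"].to_numpy(dtype=float)
        conf = g["confidence"].to_numpy(dtype=float)
        low_conf = conf < threshold
        low_vis = vis < threshold
        if low_conf.any():
            vis_rates.append(float((vis[low_conf] > threshold).mean()))
        else:
            n_ex_vis += 1
        if low_vis.any():
            conf_rates.append(float((conf[low_vis] > threshold).mean()))
        else:
            n_ex_conf += 1
    return Contingency20(
        p_vis_given_lowconf=float(np.mean(vis_rates)) if vis_rates else float("nan"),
        p_conf_given_lowvis=float(np.mean(conf_rates)) if conf_rates else float("nan"),
        n_participants=df["participant"].nunique(),
        n_excluded_vis=n_ex_vis,
        n_excluded_conf=n_ex_conf,
    )
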