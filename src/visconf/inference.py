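"""Group-level model comparison: information-criterion differences and
Jeffreys–Zellner–Siow (JZS) paired Bayes factors.

The paired design is treated as a one-sample t design on the per-participant
differences. The alternative places a Cauchy prior (default scale 1) on the
standardized effect size delta = mean difference / SD of differences; the
Bayes factor integrates the noncentral-t likelihood over that prior. The
implementation follows the standard JZS route of integrating over the
variance-scale mixture parameter g (Cauchy = scaled inverse-gamma mixture of
normals), which needs only a single well-behaved one-dimensional integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .fitting import FitResult

__all__ = [
    "DegenerateDataError",
    "PairedComparison",
    "jzs_paired_bayes_factor",
    "posterior_effect_samples",
    "hdi",
    "classify_delta",
    "bf_evidence_label",
    "compare_models",
    "EvidenceBand",
]


class DegenerateDataError(ValueError):
    """Raised when the difference scores carry no usable variance."""


def _t_statistic(diffs):
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise DegenerateDataError("need at least 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError("paired differences have zero variance")
    return d.mean() / (sd / np.sqrt(n)), n


def jzs_paired_bayes_factor(diffs, cauchy_scale: float = 1.0) -> float:
    """BF10 for a paired/one-sample t design under the JZS prior.

    Parameters
    ----------
    diffs : per-pair difference scores.
    cauchy_scale : scale of the Cauchy prior on the standardized effect size.

    Returns
    -------
    float
        Bayes factor in favor of a nonzero standardized effect.
    """
    t, n = _t_statistic(diffs)
    nu = n - 1
    r2 = cauchy_scale**2

    def integrand(g):
        # g ~ InverseGamma(1/2, r^2/2); marginal t-kernel given g
        log_prior = (
            0.5 * np.log(r2 / 2.0)
            - 0.5 * np.log(np.pi)
            - 1.5 * np.log(g)
            - r2 / (2.0 * g)
        )
        log_kernel = -0.5 * np.log1p(n * g) - 0.5 * (nu + 1) * np.log1p(
            t * t / ((1.0 + n * g) * nu)
        )
        return np.exp(log_kernel + log_prior)

    m1, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    log_m0 = -0.5 * (nu + 1) * np.log1p(t * t / nu)
    return float(m1 / np.exp(log_m0))


def _posterior_grid(diffs, cauchy_scale):
    """Grid and unnormalized posterior density of the standardized effect."""
    t, n = _t_statistic(diffs)
    nu = n - 1
    center = t / np.sqrt(n)
    half = 12.0 / np.sqrt(n) + 2.0 * abs(center) + 1.0
    grid = np.linspace(center - half, center + half, 8001)
    logpdf = stats.nct.logpdf(t, nu, grid * np.sqrt(n)) + stats.cauchy.logpdf(
        grid, scale=cauchy_scale
    )
    logpdf -= logpdf.max()
    return grid, np.exp(logpdf)


def posterior_effect_samples(
    diffs, n_samples: int = 10**6, seed: int = 0, cauchy_scale: float = 1.0
) -> np.ndarray:
    """Draw posterior samples of the standardized effect size delta.

    The posterior under the JZS model is proportional to the noncentral-t
    likelihood times the Cauchy prior; samples are drawn by inverse-CDF
    lookup on a dense grid. Deterministic given ``seed``.
    """
    grid, pdf = _posterior_grid(diffs, cauchy_scale)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    # strictly increasing support for interpolation
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n_samples)
    return np.interp(u, cdf[keep], grid[keep])


def hdi(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` posterior mass (sorted-window method)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = max(int(np.ceil(level * n)), 2)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass(frozen=True)
class EvidenceBand:
    """Signed information-criterion evidence band.

    ``direction`` is +1 when the difference favors the first model of the
    comparison, -1 for the second, 0 at exact equality.
    """

    direction: int
    label: str


#: Band edges for information-criterion differences, lower-inclusive.
DELTA_BANDS = ((0.0, "none"), (2.0, "weak"), (4.0, "moderate"), (7.0, "strong"), (10.0, "very_strong"))


def classify_delta(delta: float) -> EvidenceBand:
    """Bin an AICc/BIC difference into evidence bands.

    Bands on |delta|: [0, 2) none, [2, 4) weak, [4, 7) moderate,
    [7, 10) strong, >= 10 very strong; edges are lower-inclusive.
    """
    a = abs(delta)
    label = DELTA_BANDS[0][1]
    for edge, name in DELTA_BANDS:
        if a >= edge:
            label = name
    direction = 0 if delta == 0 else (1 if delta > 0 else -1)
    return EvidenceBand(direction, label)


def bf_evidence_label(bf10: float) -> str:
    """Strength ladder for Bayes factors (boundaries 1, 3, 10, 30, 100)."""
    b = max(bf10, 1.0 / bf10)
    for edge, name in ((100.0, "extreme"), (30.0, "very_strong"), (10.0, "strong"), (3.0, "moderate")):
        if b >= edge:
            return name
    return "anecdotal"


@dataclass
class PairedComparison:
    """Per-participant criterion differences between two fitted models.

    ``deltas`` are criterion(model_b) - criterion(model_a); positive values
    favor model a.
    """

    model_a: str
    model_b: str
    criterion: str
    deltas: np.ndarray
    mean_delta: float
    bf10: float
    hdi95: tuple[float, float]
    n: int
    evidence: str = ""

    def favors(self) -> str:
        return self.model_a if self.mean_delta > 0 else self.model_b


def compare_models(
    fits_a: dict[str, FitResult],
    fits_b: dict[str, FitResult],
    criterion: str = "aicc",
    cauchy_scale: float = 1.0,
    n_samples: int = 10**6,
    seed: int = 0,
) -> PairedComparison:
    """Paired group-level comparison of two models fitted per participant.

    ``fits_a``/``fits_b`` map participant id -> FitResult for the same
    participants. Differences are criterion(b) - criterion(a), so positive
    means model a fits better.
    """
    if criterion not in ("aicc", "bic"):
        raise ValueError("criterion must be 'aicc' or 'bic'")
    ids = sorted(fits_a)
    if sorted(fits_b) != ids:
        raise ValueError("participant sets differ between the two fit collections")
    get = (lambda f: f.aicc) if criterion == "aicc" else (lambda f: f.bic)
    deltas = np.array([get(fits_b[i]) - get(fits_a[i]) for i in ids])
    bf10 = jzs_paired_bayes_factor(deltas, cauchy_scale)
    samples = posterior_effect_samples(deltas, n_samples=n_samples, seed=seed, cauchy_scale=cauchy_scale)
    spec_a = fits_a[ids[0]].spec.label()
    spec_b = fits_b[ids[0]].spec.label()
    return PairedComparison(
        model_a=spec_a,
        model_b=spec_b,
        criterion=criterion,
        deltas=deltas,
        mean_delta=float(deltas.mean()),
        bf10=bf10,
        hdi95=hdi(samples, 0.95),
        n=len(ids),
        evidence=bf_evidence_label(bf10),
    )
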