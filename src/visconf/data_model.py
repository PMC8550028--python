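"""Trial-level data structures, rating discretization, and response tabulation.

The experiments modelled here are binary identification tasks (stimulus
identity coded -1/+1) with a graded report (visibility or confidence) given
on a continuous scale in [0, 1] and analyzed in a small number of ordered
categories. Stimulus strength is manipulated through the stimulus-onset
asynchrony (SOA) between target and mask.

Trial tables are pandas DataFrames with columns::

    participant  token identifying the observer
    soa_ms       stimulus-onset asynchrony in milliseconds
    stimulus     stimulus identity, -1 or +1
    response     identification response, -1 or +1
    rating       continuous report in [0, 1] (optional if `category` given)
    category     ordinal report category in {0, ..., n_categories - 1}
    judgment     'visibility' or 'confidence' (optional)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "ExperimentDesign",
    "CountTable",
    "EXP1_DESIGN",
    "EXP2_DESIGN",
    "discretize_rating",
    "tabulate",
    "DataError",
]

#: SOA levels (ms) of the masked-orientation experiments.
DEFAULT_SOAS_MS = (8.3, 16.7, 33.3, 66.7, 133.3)


class DataError(ValueError):
    """Raised when trial data violate the documented schema."""


@dataclass(frozen=True)
class TrialRecord:
    """A single trial of a binary identification task with a graded report."""

    participant_id: str
    soa_ms: float
    s_id: int
    r_id: int
    rating: float | None = None
    category: int | None = None
    judgment_type: str = "visibility"

    def __post_init__(self):
        if self.s_id not in (-1, 1) or self.r_id not in (-1, 1):
            raise DataError("stimulus and response must be -1 or +1")
        if self.rating is not None and not 0.0 <= self.rating <= 1.0:
            raise DataError(f"rating {self.rating} outside [0, 1]")
        if self.soa_ms <= 0:
            raise DataError("soa_ms must be positive")


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of SOAs and trial counts.

    ``trials_per_soa`` is the total number of trials at each SOA; the two
    stimulus identities split it as evenly as possible (the +1 identity
    receives the extra trial when the count is odd).
    """

    soa_levels_ms: tuple[float, ...] = DEFAULT_SOAS_MS
    trials_per_soa: int = 110
    n_categories: int = 5

    def __post_init__(self):
        soas = tuple(float(s) for s in self.soa_levels_ms)
        object.__setattr__(self, "soa_levels_ms", soas)
        if any(s <= 0 for s in soas):
            raise ValueError("SOA levels must be positive")
        if any(b >= a for a, b in zip(soas[1:], soas[:-1])):
            raise ValueError("SOA levels must be strictly increasing")
        if self.n_categories < 2:
            raise ValueError("need at least 2 rating categories")
        if self.trials_per_soa < 1:
            raise ValueError("trials_per_soa must be positive")

    @property
    def n_soa(self) -> int:
        return len(self.soa_levels_ms)

    @property
    def n_trials(self) -> int:
        return self.trials_per_soa * self.n_soa

    def trials_per_identity(self) -> tuple[int, int]:
        """Trial counts (for s_id = -1, s_id = +1) at each SOA."""
        n_minus = self.trials_per_soa // 2
        return n_minus, self.trials_per_soa - n_minus

    def soa_index(self, soa_ms) -> np.ndarray:
        """Map raw SOA values (ms) onto design level indices.

        Raw milliseconds are matched with absolute tolerance 1e-6 so that
        float round-trips through CSV cannot silently create new levels.
        """
        soa_ms = np.atleast_1d(np.asarray(soa_ms, dtype=float))
        levels = np.asarray(self.soa_levels_ms)
        dist = np.abs(soa_ms[:, None] - levels[None, :])
        idx = np.argmin(dist, axis=1)
        bad = dist[np.arange(len(soa_ms)), idx] > 1e-6
        if np.any(bad):
            raise DataError(
                f"SOA value(s) {sorted(set(soa_ms[bad]))} not in design levels "
                f"{list(levels)}"
            )
        return idx


#: Masked-orientation experiment, 11 blocks x 50 trials (10 per SOA per block).
EXP1_DESIGN = ExperimentDesign(DEFAULT_SOAS_MS, trials_per_soa=110, n_categories=5)
#: Masked-orientation experiment with dual reports, 9 blocks x 45 trials.
EXP2_DESIGN = ExperimentDesign(DEFAULT_SOAS_MS, trials_per_soa=81, n_categories=5)


def discretize_rating(rating, n_categories: int = 5):
    """Assign continuous ratings in [0, 1] to equal-width ordered categories.

    Bins are half-open ``[l, u)`` except the last, which is closed, so a
    rating of exactly 1.0 falls in the top category.

    Parameters
    ----------
    rating : float or array-like
        Continuous report(s), each in [0, 1].
    n_categories : int
        Number of equal-length partitions of the scale (>= 2).

    Returns
    -------
    int or ndarray of int
        Category index in {0, ..., n_categories - 1}.
    """
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    arr = np.asarray(rating, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise DataError("ratings must lie in [0, 1]")
    cat = np.minimum(np.floor(arr * n_categories).astype(int), n_categories - 1)
    return cat if cat.ndim else int(cat)


@dataclass
class CountTable:
    """Response frequencies indexed by (stimulus, SOA, response, category).

    ``counts[s, t, r, v]`` is the number of trials with stimulus identity
    ``(-1, +1)[s]`` at SOA index ``t`` answered with identification response
    ``(-1, +1)[r]`` and rating category ``v``.
    """

    design: ExperimentDesign
    counts: np.ndarray = field(default=None)

    def __post_init__(self):
        shape = (2, self.design.n_soa, 2, self.design.n_categories)
        if self.counts is None:
            self.counts = np.zeros(shape, dtype=np.int64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != shape:
                raise ValueError(f"counts must have shape {shape}")
            if np.any(self.counts < 0):
                raise ValueError("counts must be nonnegative")

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())

    def per_condition_totals(self) -> np.ndarray:
        """Trial totals per (stimulus, SOA) condition, shape (2, n_soa)."""
        return self.counts.sum(axis=(2, 3))


def tabulate(trials: pd.DataFrame, design: ExperimentDesign) -> CountTable:
    """Tabulate trial records into a (stimulus, SOA, response, category) table.

    Trials must carry a ``category`` column or a continuous ``rating`` column
    (discretized here with the design's category count).
    """
    table = CountTable(design)
    if len(trials) == 0:
        return table
    for col in ("soa_ms", "stimulus", "response"):
        if col not in trials.columns:
            raise DataError(f"missing required column '{col}'")
    s = np.asarray(trials["stimulus"], dtype=int)
    r = np.asarray(trials["response"], dtype=int)
    if not (np.all(np.isin(s, (-1, 1))) and np.all(np.isin(r, (-1, 1)))):
        raise DataError("stimulus and response must be -1 or +1")
    if "category" in trials.columns and trials["category"].notna().all():
        v = np.asarray(trials["category"], dtype=int)
        if np.any(v < 0) or np.any(v >= design.n_categories):
            raise DataError("category outside design range")
    elif "rating" in trials.columns:
        v = discretize_rating(np.asarray(trials["rating"]), design.n_categories)
    else:
        raise DataError("trials need a 'category' or 'rating' column")
    t = design.soa_index(np.asarray(trials["soa_ms"], dtype=float))
    si = ((s + 1) // 2).astype(int)
    ri = ((r + 1) // 2).astype(int)
    np.add.at(table.counts, (si, t, ri, v), 1)
    return table
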