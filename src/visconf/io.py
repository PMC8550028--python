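"""CSV schemas, manifests, and bit-stable serialization helpers.

Column dictionary for trial tables (all CSVs carry a header):

=============  =====================================================
participant    observer identifier (string)
soa_ms         stimulus-onset asynchrony in milliseconds
stimulus       stimulus identity, -1 or +1
response       identification response, -1 or +1
rating         continuous report in [0, 1] (optional)
category       ordinal report category (optional; at least one of
               rating/category must be present)
judgment       'visibility' or 'confidence' (optional)
=============  =====================================================

Fit summaries are tidy CSVs with one row per participant x model x variance
mode (participant, family, variance_mode, k_free, n_trials, negll, aicc, bic,
converged, params_json).
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .data_model import DataError
from .fitting import FitResult
from .models import ModelSpec, ParameterSet

__all__ = [
    "read_trials",
    "write_trials",
    "write_manifest",
    "fits_to_frame",
    "frame_to_fits",
    "params_to_json",
    "params_from_json",
]

_REQUIRED = ("participant", "soa_ms", "stimulus", "response")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Raises :class:`~visconf.data_model.DataError` naming the offending
    file/column/row on schema violations.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise DataError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in _REQUIRED:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column '{col}'")
    if "rating" not in df.columns and "category" not in df.columns:
        raise DataError(f"{path}: need a 'rating' or 'category' column")
    for col, check in (
        ("soa_ms", lambda v: np.isfinite(v) & (v > 0)),
        ("stimulus", lambda v: np.isin(v, (-1, 1))),
        ("response", lambda v: np.isin(v, (-1, 1))),
    ):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~check(vals.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise DataError(f"{path}: invalid value in column '{col}' at line {row}")
        df[col] = vals
    if "rating" in df.columns:
        vals = pd.to_numeric(df["rating"], errors="coerce")
        bad = (~np.isfinite(vals)) | (vals < 0) | (vals > 1)
        if bad.to_numpy().any():
            row = int(np.flatnonzero(bad)[0]) + 2
            raise DataError(f"{path}: invalid value in column 'rating' at line {row}")
        df["rating"] = vals
    df["stimulus"] = df["stimulus"].astype(int)
    df["response"] = df["response"].astype(int)
    return df


def write_trials(trials: pd.DataFrame, path):
    """Write a trial table with stable column order and float formatting."""
    cols = [c for c in ("participant", "soa_ms", "stimulus", "response", "rating", "category", "judgment") if c in trials.columns]
    trials.to_csv(path, index=False, columns=cols, float_format="%.10g")


def write_manifest(path, config: dict, seed: int | None = None):
    """Write a JSON manifest (config echo, seed, environment summary)."""
    manifest = {
        "config": config,
        "seed": seed,
        "package": {"name": "visconf", "version": __version__},
        "python": platform.python_version(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def params_to_json(params: ParameterSet) -> str:
    d = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in asdict(params).items() if v is not None}
    return json.dumps(d, sort_keys=True)


def params_from_json(text: str) -> ParameterSet:
    return ParameterSet(**json.loads(text))


def fits_to_frame(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Tidy one-row-per-fit summary (with parameters as a JSON column)."""
    rows = []
    for pid in sorted(fits):
        f = fits[pid]
        rows.append(
            {
                "participant": pid,
                "family": f.spec.family,
                "variance_mode": f.spec.variance_mode,
                "k_free": f.k_free,
                "n_trials": f.n_trials,
                "negll": f.neg_log_likelihood,
                "aicc": f.aicc,
                "bic": f.bic,
                "converged": f.converged,
                "params_json": params_to_json(f.params),
            }
        )
    return pd.DataFrame(rows)


def frame_to_fits(df: pd.DataFrame) -> dict[str, FitResult]:
    """Rebuild FitResult objects from a tidy fit summary."""
    fits = {}
    for _, row in df.iterrows():
        spec = ModelSpec(row["family"], row["variance_mode"])
        fits[str(row["participant"])] = FitResult(
            spec=spec,
            params=params_from_json(row["params_json"]),
            neg_log_likelihood=float(row["negll"]),
            aicc=float(row["aicc"]),
            bic=float(row["bic"]),
            n_trials=int(row["n_trials"]),
            k_free=int(row["k_free"]),
            converged=bool(row["converged"]),
        )
    return fits
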