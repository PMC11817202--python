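"""Hjorth parameters and the epoch-level feature table.

For a discrete signal x(n), n = 1..N:

* activity   = Var(x) with the 1/N normalization — the signal's power;
* mobility   = sqrt(Var(Δx) / Var(x)), with Δx the first difference
  (length N−1, no division by the sampling interval, so mobility is in
  per-sample units; for a sampled sinusoid of frequency f it equals
  2·sin(πf/fs));
* complexity = mobility(Δx) / mobility(x) — ≈ 1 for a pure sinusoid,
  larger for less regular signals.

Degenerate conventions (keep tables total, never emit NaN): Var(x)=0
yields (0, 0, 0) with a warning; Var(Δx)=0 with Var(x)>0 (e.g. a
linear ramp) yields mobility 0 and complexity 0.
"""

import warnings
from typing import Dict, NamedTuple

import numpy as np
import pandas as pd

from .bands import sort_band_names
from .errors import AlignmentError, SignalTooShortError
from .io import PARAMETERS, feature_name
from .recording import EpochSet


class HjorthTriple(NamedTuple):
    activity: float
    mobility: float
    complexity: float


def _var(x: np.ndarray, axis=-1) -> np.ndarray:
    return np.var(x, axis=axis)  # 1/N normalization


def hjorth(x) -> HjorthTriple:
    """Hjorth activity, mobility and complexity of one signal vector."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise SignalTooShortError("hjorth needs a 1-D signal of length >= 3")
    a, m, c = hjorth_nd(x[np.newaxis, :])
    return HjorthTriple(float(a[0]), float(m[0]), float(c[0]))


def hjorth_nd(x: np.ndarray, axis: int = -1):
    """Vectorized Hjorth parameters along ``axis``; returns (act, mob, comp)."""
    x = np.moveaxis(np.asarray(x, dtype=np.float64), axis, -1)
    if x.shape[-1] < 3:
        raise SignalTooShortError("hjorth needs length >= 3 along the signal axis")
    d1 = np.diff(x, axis=-1)
    d2 = np.diff(d1, axis=-1)
    v0, v1, v2 = _var(x), _var(d1), _var(d2)
    if np.any(v0 == 0):
        warnings.warn("zero-variance signal(s): Hjorth triple set to (0, 0, 0)")

    def _safe_ratio(num, den):
        out = np.zeros(np.broadcast_shapes(np.shape(num), np.shape(den)))
        ok = den > 0
        np.divide(num, den, out=out, where=ok)
        return out

    mobility = np.sqrt(_safe_ratio(v1, v0))
    mob_d1 = np.sqrt(_safe_ratio(v2, v1))
    complexity = _safe_ratio(mob_d1, mobility)
    return v0, mobility, complexity


def extract_features(per_band: Dict[str, EpochSet]) -> pd.DataFrame:
    """Feature table of one subject: one row per epoch.

    ``per_band`` maps band name → that band's epoch set; all sets must
    share epoch count and channels. Columns are canonical —
    ``subject_id, group, epoch`` then ``<band>.<param>.<channel>`` in
    band-major / parameter / channel order.
    """
    if not per_band:
        raise AlignmentError("no bands supplied")
    names = sort_band_names(per_band.keys())
    first = per_band[names[0]]
    for n in names:
        es = per_band[n]
        if es.n_epochs != first.n_epochs or es.channels != first.channels:
            raise AlignmentError(
                f"band {n!r} epochs/channels inconsistent with band {names[0]!r}"
            )
    columns = {
        "subject_id": np.repeat(first.subject_id, first.n_epochs),
        "group": np.repeat(first.group, first.n_epochs),
        "epoch": np.arange(first.n_epochs),
    }
    for n in names:
        es = per_band[n]
        act, mob, comp = hjorth_nd(es.data)  # (epoch, channel)
        per_param = dict(zip(PARAMETERS, (act, mob, comp)))
        for p in PARAMETERS:
            for ci, ch in enumerate(es.channels):
                columns[feature_name(n, p, ch)] = per_param[p][:, ci]
    return pd.DataFrame(columns)


def cohort_feature_table(per_subject_tables) -> pd.DataFrame:
    """Concatenate per-subject tables; column sets must agree exactly."""
    tables = list(per_subject_tables)
    cols = list(tables[0].columns)
    for t in tables[1:]:
        if list(t.columns) != cols:
            raise AlignmentError("subject feature tables have differing columns")
    return pd.concat(tables, ignore_index=True)
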