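"""Per-subject correlation matrices and the Fisher-z group connectome.

Pearson correlation matrices are computed per subject from parcellated BOLD
time series, z-transformed with atanh, averaged element-wise across subjects,
and back-transformed with tanh. The unit diagonal is excluded from the z
transform (atanh(1) is infinite) and restored afterwards.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .core_io import ConnectivityMatrix

__all__ = ["correlate", "fisher_z", "fisher_z_inv", "group_average", "regress_motion"]

log = logging.getLogger(__name__)

# |r| at or above this is clipped (with a warning) instead of erroring, so
# degenerate synthetic duplicates do not abort a cohort run.
_CLIP = 1.0 - 1e-12


def correlate(ts: np.ndarray, parcel_ids: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Pearson correlation matrix of a T × P parcellated time-series array.

    Raises if T < 3 or any parcel has zero temporal variance (the error names
    the parcel). Off-diagonal |r| ≥ 1 − 1e-12 (duplicate or anti-duplicate
    columns) is clipped to ±(1 − 1e-12) with a logged warning.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be 2-D (T × P)")
    n_t, n_p = ts.shape
    if n_t < 3:
        raise ValueError(f"need at least 3 time points, got {n_t}")
    ids = tuple(parcel_ids) if parcel_ids is not None else tuple(f"p{i}" for i in range(n_p))
    sd = ts.std(axis=0)
    if (sd == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance parcel time series: {bad}")
    r = np.corrcoef(ts, rowvar=False)
    off = ~np.eye(n_p, dtype=bool)
    n_clip = int(np.count_nonzero(np.abs(r[off]) >= _CLIP))
    if n_clip:
        log.warning("clipped %d off-diagonal correlations with |r| >= 1-1e-12", n_clip)
        r[off] = np.clip(r[off], -_CLIP, _CLIP)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(values=r, parcel_ids=ids)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z transform, z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1.0).any():
        raise ValueError("fisher_z requires |r| < 1 (exclude the diagonal)")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z: np.ndarray | float) -> np.ndarray | float:
    """Inverse Fisher transform, r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def group_average(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean in Fisher-z space, back-transformed to r.

    All matrices must share the same parcel order. The diagonal is excluded
    from the transform and restored as 1.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    ids = matrices[0].parcel_ids
    n_p = matrices[0].n_parcels
    for m in matrices[1:]:
        if m.parcel_ids != ids:
            raise ValueError("parcel order mismatch between subjects")
    off = ~np.eye(n_p, dtype=bool)
    acc = np.zeros((n_p, n_p))
    for m in matrices:
        z = np.zeros_like(acc)
        z[off] = np.arctanh(m.values[off])
        acc += z
    acc /= len(matrices)
    avg = np.zeros_like(acc)
    avg[off] = np.tanh(acc[off])
    np.fill_diagonal(avg, 1.0)
    avg = (avg + avg.T) / 2.0
    return ConnectivityMatrix(values=avg, parcel_ids=ids)


def regress_motion(ts: np.ndarray, motion: np.ndarray) -> np.ndarray:
    """Residualize each parcel time series on motion traces (OLS, intercept).

    ``motion`` is T × M (typically the 12 realignment-parameter traces);
    exactly the supplied columns are regressed out, with no derivative or
    squared expansions.
    """
    ts = np.asarray(ts, dtype=float)
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[0] != ts.shape[0]:
        raise ValueError("motion traces must be T × M with T matching the time series")
    design = np.column_stack([np.ones(ts.shape[0]), motion])
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ beta
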