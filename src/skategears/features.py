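"""Time-normalized cross-correlation features of one movement cycle.

Each cycle's local-frame head displacement is resampled to 12 equispaced
points on [t_start, t_end) — half-open, so the wrap point is not duplicated
— and mean-centred per component. The fore-aft and vertical components are
then circularly cross-correlated with the sideways component at lags
-6..+6, normalized by the product of the component norms. Concatenating the
two 13-point waveforms gives a 26-dimensional descriptor that is invariant
to positive rescaling of any component (hence robust to speed and
anthropometric differences) and exactly antisymmetric under left/right
mirroring of the movement.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .containers import CycleRecord, LocalFrameSeries


class FeatureUndefinedError(ValueError):
    """Raised when a correlation feature has no defined value (zero norm)."""


def resample_cycle(time: np.ndarray, pos_lcs: np.ndarray, t_start: float,
                   t_end: float, n_points: int = 12) -> Optional[np.ndarray]:
    """Linear interpolation of each LCS component at ``n_points`` equispaced
    instants spanning [t_start, t_end), mean removed per component.

    Returns None (with a warning) if the cycle holds fewer than ``n_points``
    samples.
    """
    time = np.asarray(time, dtype=float)
    inside = np.count_nonzero((time >= t_start - 1e-9) & (time <= t_end + 1e-9))
    if inside < n_points:
        warnings.warn(f"cycle [{t_start:.3f}, {t_end:.3f}] has {inside} "
                      f"samples (< {n_points}); dropped", stacklevel=2)
        return None
    grid = t_start + (t_end - t_start) * np.arange(n_points) / n_points
    out = np.column_stack([np.interp(grid, time, pos_lcs[:, k])
                           for k in range(pos_lcs.shape[1])])
    return out - out.mean(axis=0)


def _circular_corr(x: np.ndarray, y: np.ndarray, max_lag: int,
                   normalized: bool) -> np.ndarray:
    """c[l] = sum_k x[k] * y[(k+l) mod n] for l = -max_lag..max_lag."""
    n = x.size
    lags = np.arange(-max_lag, max_lag + 1)
    c = np.array([float(np.dot(x, np.roll(y, -l))) for l in lags])
    if normalized:
        denom = float(np.linalg.norm(x) * np.linalg.norm(y))
        if denom == 0.0:
            raise FeatureUndefinedError(
                "cross-correlation undefined for a zero-norm component")
        c = c / denom
    return c


def _linear_corr(x: np.ndarray, y: np.ndarray, max_lag: int,
                 normalized: bool) -> np.ndarray:
    lags = np.arange(-max_lag, max_lag + 1)
    c = np.empty(lags.size)
    for i, l in enumerate(lags):
        if l >= 0:
            c[i] = float(np.dot(x[: x.size - l], y[l:]))
        else:
            c[i] = float(np.dot(x[-l:], y[: y.size + l]))
    if normalized:
        denom = float(np.linalg.norm(x) * np.linalg.norm(y))
        if denom == 0.0:
            raise FeatureUndefinedError(
                "cross-correlation undefined for a zero-norm component")
        c = c / denom
    return c


def xcorr_features(cycle12: np.ndarray, max_lag: int = 6,
                   normalized: bool = True,
                   circular: bool = True) -> np.ndarray:
    """26-value feature vector: fore-aft x sideways waveform (13 lags)
    followed by vertical x sideways waveform (13 lags).

    ``normalized``/``circular`` switch to raw or linear-boundary correlation
    for ablation; the defaults are the pipeline's convention.
    """
    cycle12 = np.asarray(cycle12, dtype=float)
    if cycle12.ndim != 2 or cycle12.shape[1] != 3:
        raise ValueError("cycle array must have shape (n, 3)")
    fore, side, vert = cycle12[:, 0], cycle12[:, 1], cycle12[:, 2]
    corr = _circular_corr if circular else _linear_corr
    w_fore = corr(fore, side, max_lag, normalized)
    w_vert = corr(vert, side, max_lag, normalized)
    return np.concatenate([w_fore, w_vert])


def features_for_cycles(
    lcs: LocalFrameSeries, records: Sequence[CycleRecord],
    n_points: int = 12, max_lag: int = 6,
) -> Tuple[np.ndarray, List[int]]:
    """Feature matrix for the cycles that survive resampling.

    Returns the (m, 2*(2*max_lag+1)) matrix and the indices of the kept
    records.
    """
    rows, kept = [], []
    for i, rec in enumerate(records):
        cyc = resample_cycle(lcs.time, lcs.pos_lcs, rec.t_start, rec.t_end,
                             n_points)
        if cyc is None:
            continue
        rows.append(xcorr_features(cyc, max_lag=max_lag))
        kept.append(i)
    if not rows:
        return np.empty((0, 2 * (2 * max_lag + 1))), []
    return np.vstack(rows), kept


__all__ = ["FeatureUndefinedError", "resample_cycle", "xcorr_features",
           "features_for_cycles"]
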