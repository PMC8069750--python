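"""Trajectory denoising and local-coordinate-system construction.

The raw 50 Hz head trajectory is smoothed per axis with a cubic smoothing
spline whose penalty is tuned (by bisection on log-lambda) until the RMS
residual matches the expected measurement noise — the standard way of
filtering kinematic dGNSS solutions when the noise level is known. Velocity
comes from the analytic derivative of the fitted spline rather than finite
differences, so position noise is not re-amplified.

The local coordinate system (LCS) rides on the 0.3 Hz low-pass head
trajectory (5th-order zero-phase Butterworth): the cutoff removes the
0.5-1 Hz propulsion oscillations while keeping the slower progression
through the course. Skiing direction is the normalized origin velocity,
vertical is global up, and sideways is their cross product (pointing to the
skier's right). Cycle detection runs on the sideways component of the head
velocity expressed in this frame.

Float-ambiguity samples are never bridged: every operation works on
contiguous fixed-flag blocks and short blocks are dropped with a warning.
"""

from __future__ import annotations

import warnings
from typing import List, Optional

import numpy as np
from scipy.interpolate import UnivariateSpline, make_smoothing_spline
from scipy.signal import butter, sosfiltfilt

from .containers import LocalFrameSeries, TrajectorySeries

_UP = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# block handling
# ---------------------------------------------------------------------------

def contiguous_blocks(traj: TrajectorySeries, min_len: int = 2,
                      use_fix: bool = True) -> List[slice]:
    """Slices of maximal runs that are fixed-flag and uniformly sampled.

    A gap larger than 1.5 nominal sample intervals splits a block, so series
    from which float samples were removed fall apart at the removal points.
    """
    if traj.n == 0:
        return []
    dt_nom = 1.0 / traj.sample_rate if traj.n > 1 else 0.0
    brk = np.zeros(traj.n, dtype=bool)
    brk[0] = True
    if traj.n > 1:
        brk[1:] = np.diff(traj.time) > 1.5 * dt_nom
    if use_fix:
        flips = np.zeros(traj.n, dtype=bool)
        flips[1:] = traj.fix[1:] != traj.fix[:-1]
        brk |= flips
    starts = np.flatnonzero(brk)
    bounds = np.append(starts, traj.n)
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if (not use_fix or traj.fix[a]) and b - a >= min_len:
            out.append(slice(int(a), int(b)))
    return out


# ---------------------------------------------------------------------------
# smoothing spline
# ---------------------------------------------------------------------------

def _fit_axis(t: np.ndarray, y: np.ndarray, target_rms: float):
    """Cubic smoothing spline with residual RMS ~= target_rms.

    The discrepancy criterion (residual sum of squares = n * sd^2) maps
    directly onto the ``s`` parameter of a FITPACK smoothing spline, which
    also places knots adaptively. If FITPACK fails, fall back to a
    penalized smoothing spline with the penalty found by bisection on
    log10(lambda); if even maximal smoothing leaves residuals below target
    (e.g., straight-line data, which a spline fits exactly at any penalty)
    the heaviest smoothing is used.
    """
    if target_rms <= 0:
        return make_smoothing_spline(t, y, lam=0.0)
    try:
        return UnivariateSpline(t, y, k=3, s=y.size * target_rms ** 2)
    except Exception:
        pass

    def rms(lam: float) -> float:
        spl = make_smoothing_spline(t, y, lam=lam)
        return float(np.sqrt(np.mean((spl(t) - y) ** 2)))

    # upper cap: far above the operating penalty for 50 Hz kinematics but
    # small enough that the banded solve stays well conditioned
    lo, hi = -14.0, 2.0
    if rms(10.0 ** lo) >= target_rms:
        return make_smoothing_spline(t, y, lam=10.0 ** lo)
    if rms(10.0 ** hi) <= target_rms:
        return make_smoothing_spline(t, y, lam=10.0 ** hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        r = rms(10.0 ** mid)
        if abs(r - target_rms) < 0.002 * target_rms:
            lo = hi = mid
            break
        if r < target_rms:
            lo = mid
        else:
            hi = mid
    return make_smoothing_spline(t, y, lam=10.0 ** (0.5 * (lo + hi)))


def smooth_spline(traj: TrajectorySeries, expected_noise_sd: float,
                  min_block: int = 10) -> TrajectorySeries:
    """Per-block, per-axis smoothing spline fit of the fixed-flag samples.

    Returns a trajectory holding only the retained samples, re-evaluated on
    an exact uniform grid per block, with spline-derivative velocity filled
    in. Float gaps remain as time gaps; blocks shorter than ``min_block``
    samples are dropped with a warning.
    """
    blocks = contiguous_blocks(traj, min_len=2)
    times, poss, vels = [], [], []
    fs = traj.sample_rate
    for sl in blocks:
        if sl.stop - sl.start < min_block:
            warnings.warn(
                f"dropping fixed block of {sl.stop - sl.start} samples "
                f"(< {min_block})", stacklevel=2)
            continue
        t = traj.time[sl]
        # exact uniform 50 Hz grid over the block span
        n_out = int(np.floor((t[-1] - t[0]) * fs + 0.5)) + 1
        t_out = t[0] + np.arange(n_out) / fs
        p_out = np.empty((n_out, 3))
        v_out = np.empty((n_out, 3))
        for ax in range(3):
            spl = _fit_axis(t, traj.pos[sl, ax], expected_noise_sd)
            p_out[:, ax] = spl(t_out)
            v_out[:, ax] = spl.derivative()(t_out)
        times.append(t_out)
        poss.append(p_out)
        vels.append(v_out)
    if not times:
        raise ValueError("no fixed-flag block of sufficient length")
    return TrajectorySeries(np.concatenate(times), np.vstack(poss),
                            np.ones(sum(x.size for x in times), dtype=bool),
                            vel=np.vstack(vels))


# ---------------------------------------------------------------------------
# low-pass origin
# ---------------------------------------------------------------------------

def lowpass_trajectory(traj: TrajectorySeries, cutoff: float = 0.3,
                       order: int = 5,
                       min_settle_factor: float = 3.0) -> TrajectorySeries:
    """Zero-phase Butterworth low-pass of each axis, per contiguous block.

    Blocks shorter than ``min_settle_factor`` times the settling length
    (taken as one cutoff period, fs/cutoff samples) are dropped with a
    warning: the bidirectional filter is unreliable on them.
    """
    fs = traj.sample_rate
    sos = butter(order, cutoff, btype="low", fs=fs, output="sos")
    n_settle = int(round(fs / cutoff))
    times, poss = [], []
    for sl in contiguous_blocks(traj, min_len=2):
        n = sl.stop - sl.start
        if n < min_settle_factor * n_settle:
            warnings.warn(
                f"dropping block of {n} samples, shorter than "
                f"{min_settle_factor}x the {n_settle}-sample filter settling "
                "length", stacklevel=2)
            continue
        times.append(traj.time[sl])
        # remove the linear trend (the progression) before filtering and add
        # it back: the trend passes a DC-gain-1 filter anyway, and keeping it
        # out of the filter suppresses the slow edge transients of a cutoff
        # this low; pad with ~3 cutoff periods (the default padlen is far too
        # short here)
        t_blk = traj.time[sl] - traj.time[sl.start]
        p_blk = traj.pos[sl]
        coef = np.polynomial.polynomial.polyfit(t_blk, p_blk, 1)
        trend = np.polynomial.polynomial.polyval(t_blk, coef).T
        padlen = min(n - 1, 3 * n_settle)
        poss.append(trend + sosfiltfilt(sos, p_blk - trend, axis=0,
                                        padlen=padlen))
    if not times:
        raise ValueError("no block long enough for the low-pass filter")
    t = np.concatenate(times)
    return TrajectorySeries(t, np.vstack(poss), np.ones(t.size, dtype=bool))


# ---------------------------------------------------------------------------
# local coordinate system
# ---------------------------------------------------------------------------

def build_lcs(smooth: TrajectorySeries, origin: TrajectorySeries,
              min_speed: float = 0.1) -> LocalFrameSeries:
    """Express the smoothed head trajectory in the moving local frame.

    Both inputs must share a time base (the smoothed series is trimmed to
    the samples present in the origin series, which may have dropped short
    blocks). Samples where the origin moves slower than ``min_speed`` have
    an undefined skiing direction and are flagged invalid.
    """
    if origin.n < smooth.n:
        keep = np.isin(np.round(smooth.time * 1e6).astype(np.int64),
                       np.round(origin.time * 1e6).astype(np.int64))
        smooth = smooth.slice(np.flatnonzero(keep)) if keep.sum() else smooth
    if smooth.n != origin.n or not np.allclose(smooth.time, origin.time,
                                               atol=1e-9):
        raise ValueError("smooth and origin series must share a time base")

    t = origin.time
    n = t.size
    v_o = np.empty((n, 3))
    heading = np.empty(n)
    for sl in contiguous_blocks(origin, min_len=2, use_fix=False):
        v_o[sl] = np.gradient(origin.pos[sl], t[sl], axis=0)
    speed = np.linalg.norm(v_o, axis=1)
    valid = speed >= min_speed

    with np.errstate(invalid="ignore", divide="ignore"):
        e_ski = v_o / np.where(speed > 0, speed, np.nan)[:, None]
    e_ski = np.where(np.isfinite(e_ski), e_ski, 0.0)
    e_side = np.cross(e_ski, _UP)
    side_norm = np.linalg.norm(e_side, axis=1)
    valid &= side_norm > 1e-6  # purely vertical motion has no sideways axis
    with np.errstate(invalid="ignore", divide="ignore"):
        e_side = e_side / np.where(side_norm > 0, side_norm, np.nan)[:, None]
    e_side = np.where(np.isfinite(e_side), e_side, 0.0)
    e_vert = np.tile(_UP, (n, 1))

    rel = smooth.pos - origin.pos
    pos_lcs = np.column_stack([
        np.einsum("ij,ij->i", rel, e_ski),
        np.einsum("ij,ij->i", rel, e_side),
        np.einsum("ij,ij->i", rel, e_vert),
    ])
    vel_lcs = np.empty_like(pos_lcs)
    for sl in contiguous_blocks(origin, min_len=2, use_fix=False):
        vel_lcs[sl] = np.gradient(pos_lcs[sl], t[sl], axis=0)
        az = np.degrees(np.arctan2(e_ski[sl, 0], e_ski[sl, 1]))
        heading[sl] = np.degrees(np.unwrap(np.radians(az)))

    return LocalFrameSeries(time=t, origin=origin.pos, e_ski=e_ski,
                            e_side=e_side, e_vert=e_vert, pos_lcs=pos_lcs,
                            vel_lcs=vel_lcs, heading_deg=heading, valid=valid)


__all__ = ["contiguous_blocks", "smooth_spline", "lowpass_trajectory",
           "build_lcs"]
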