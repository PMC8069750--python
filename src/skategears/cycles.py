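"""Movement-cycle detection and per-cycle metrics.

A movement cycle is one full sideways oscillation of the body, delimited by
successive peaks of the sideways head velocity in the local frame. Peaks
must have a topographic prominence of at least 0.7 m/s and be separated by
at least 0.8 s; among closer peaks the higher one wins (ties go to the
earlier peak). Cycle duration is the time between boundaries and cycle
length the straight-line (chord) displacement of the smoothed Earth-frame
position between them. The per-cycle heading rate — input to the Turn rule —
is the absolute net change of skiing-direction azimuth divided by duration.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .containers import CycleRecord, LocalFrameSeries, TrajectorySeries
from .preprocess import contiguous_blocks


def detect_cycles(time: np.ndarray, vel_side: np.ndarray,
                  prominence: float = 0.7, min_separation: float = 0.8,
                  valid: Optional[np.ndarray] = None) -> np.ndarray:
    """Cycle boundary times within one contiguous block.

    Local maxima with prominence >= ``prominence`` are candidates (block
    endpoints act as infinite-depth valleys, the standard topographic
    convention); candidates closer than ``min_separation`` are thinned
    greedily, keeping the higher peak and, on ties, the earlier one.
    """
    time = np.asarray(time, dtype=float)
    v = np.asarray(vel_side, dtype=float)
    if v.size < 3:
        return np.empty(0)
    peaks, _ = find_peaks(v, prominence=prominence)
    if valid is not None:
        peaks = peaks[np.asarray(valid, dtype=bool)[peaks]]
    if peaks.size == 0:
        return np.empty(0)
    # greedy separation: height descending, earlier index breaks ties
    order = np.lexsort((peaks, -v[peaks]))
    accepted: List[int] = []
    for idx in peaks[order]:
        if all(abs(time[idx] - time[j]) >= min_separation for j in accepted):
            accepted.append(idx)
    return time[np.sort(accepted)]


def measure_cycles(boundaries: Sequence[float], smooth: TrajectorySeries,
                   lcs: LocalFrameSeries) -> List[CycleRecord]:
    """One record per adjacent boundary pair.

    Cycles containing invalid-frame samples, or whose boundaries fall
    outside the trajectory support, are skipped (this also discards cycles
    that would span a float-ambiguity gap, since blocks are detected
    independently).
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if boundaries.size < 2:
        return []
    records: List[CycleRecord] = []
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        i0 = int(np.searchsorted(smooth.time, t0 - 1e-9))
        i1 = int(np.searchsorted(smooth.time, t1 + 1e-9))
        if i0 >= smooth.n or i1 > smooth.n or i1 <= i0:
            continue
        # boundaries must lie inside one contiguous block of the series
        seg_t = smooth.time[i0:i1]
        if np.any(np.diff(seg_t) > 1.5 / smooth.sample_rate):
            continue
        if not np.all(lcs.valid[i0:i1]):
            continue
        p0 = _interp_vec(smooth.time, smooth.pos, t0)
        p1 = _interp_vec(smooth.time, smooth.pos, t1)
        length = float(np.linalg.norm(p1 - p0))
        h0 = float(np.interp(t0, lcs.time, lcs.heading_deg))
        h1 = float(np.interp(t1, lcs.time, lcs.heading_deg))
        duration = float(t1 - t0)
        records.append(CycleRecord(
            t_start=float(t0), t_end=float(t1), duration=duration,
            length=length, heading_change=h1 - h0,
            heading_rate=abs(h1 - h0) / duration))
    return records


def _interp_vec(t: np.ndarray, x: np.ndarray, ti: float) -> np.ndarray:
    return np.array([np.interp(ti, t, x[:, k]) for k in range(x.shape[1])])


def average_over_n(records: Sequence[CycleRecord],
                   n: int) -> List[Tuple[float, float]]:
    """(mean duration, mean length) over non-overlapping blocks of ``n``
    successive cycles; incomplete trailing blocks are discarded.

    For contiguous cycles the block-mean duration telescopes to
    (t_end_block - t_start_block) / n, which is asserted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out: List[Tuple[float, float]] = []
    for k in range(0, len(records) - n + 1, n):
        block = records[k:k + n]
        mean_dur = float(np.mean([r.duration for r in block]))
        mean_len = float(np.mean([r.length for r in block]))
        contiguous = all(abs(a.t_end - b.t_start) < 1e-9
                         for a, b in zip(block[:-1], block[1:]))
        if contiguous:
            span = (block[-1].t_end - block[0].t_start) / n
            assert abs(span - mean_dur) < 1e-9
        out.append((mean_dur, mean_len))
    return out


def block_duration_deviations(boundaries: np.ndarray,
                              truth_events: np.ndarray, n: int = 1,
                              match_tol: float = 0.35) -> np.ndarray:
    """Relative deviations of n-cycle mean durations from ground truth.

    Each detected boundary is paired with its nearest true event (within
    ``match_tol`` seconds). For every non-overlapping block of ``n``
    successive detected cycles whose end boundaries map to true events
    exactly ``n`` cycles apart, the relative deviation of the block-mean
    duration is returned. Because the block mean telescopes to
    (last - first boundary) / n, boundary errors at interior cycles cancel
    — the mechanism behind the faster-than-N^{-1/2} error reduction of
    cycle averaging.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    truth_events = np.asarray(truth_events, dtype=float)
    if boundaries.size < n + 1 or truth_events.size < 2:
        return np.empty(0)
    pos = np.searchsorted(truth_events, boundaries)
    mapped = np.full(boundaries.size, -1)
    for i, (b, p) in enumerate(zip(boundaries, pos)):
        cands = [j for j in (p - 1, p) if 0 <= j < truth_events.size]
        if not cands:
            continue
        j = min(cands, key=lambda j: abs(truth_events[j] - b))
        if abs(truth_events[j] - b) <= match_tol:
            mapped[i] = j
    out = []
    k = 0
    while k + n < boundaries.size:
        j0, j1 = mapped[k], mapped[k + n]
        if j0 >= 0 and j1 == j0 + n:
            mean_det = (boundaries[k + n] - boundaries[k]) / n
            mean_true = (truth_events[j1] - truth_events[j0]) / n
            out.append(mean_det / mean_true - 1.0)
            k += n
        else:
            k += 1
    return np.asarray(out)


__all__ = ["detect_cycles", "measure_cycles", "average_over_n",
           "block_duration_deviations"]

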