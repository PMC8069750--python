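"""Sub-technique classification: spectral gates, hard rules and the NNC.

The decision tree runs in fixed precedence order:

1. **Tuck** — time intervals where the 0.5-1.0 Hz band sum of the sideways
   head velocity (short-time Fourier transform, 256-sample Hanning window,
   512-point FFT, 255-sample overlap) is below ``T_tuck`` (40 m/s): a static
   crouch has no sideways oscillation, so cycle detection is not applicable.
2. **Turn** — detected cycles whose heading rate exceeds ``T_turn``
   (10 deg/s).
3. **G5** — remaining cycles whose mean vertical 0.5-1.5 Hz band sum is
   below ``T_G5`` (100 m/s): skating without poles barely moves the head
   vertically.
4. **NNC** — everything else goes to a 26-15-5 feed-forward network on the
   cross-correlation features, whose left/right output classes are merged
   (G2L/G2R -> G2, G4L/G4R -> G4).

Band sums use the one-sided magnitude spectrum of the Hanning-windowed
velocity with no window-gain or length normalization, summed over the bins
whose centre frequency lies in the closed band; the thresholds are
calibrated to exactly this convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import fftconvolve, get_window

from .config import PipelineConfig, StftConfig, Thresholds
from .containers import (CycleRecord, GroundTruth, LocalFrameSeries,
                         TrajectorySeries, merge_label, records_to_frame)
from .cycles import detect_cycles, measure_cycles
from .features import features_for_cycles
from .preprocess import (build_lcs, contiguous_blocks, lowpass_trajectory,
                         smooth_spline)

MERGE_MAP = {"G2L": "G2", "G2R": "G2", "G3": "G3", "G4L": "G4", "G4R": "G4"}


# ---------------------------------------------------------------------------
# short-time Fourier transform band summaries
# ---------------------------------------------------------------------------

@dataclass
class SpectralSummary:
    """Per-frame band-magnitude sums; one frame per hop, timestamped at the
    window centre."""

    times: np.ndarray
    band_side: np.ndarray  # m/s, sideways 0.5-1.0 Hz
    band_vert: np.ndarray  # m/s, vertical 0.5-1.5 Hz


def _band_bins(fs: float, nfft: int, band: Tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return np.flatnonzero((freqs >= band[0] - 1e-12)
                          & (freqs <= band[1] + 1e-12))


def _band_sum(x: np.ndarray, w: np.ndarray, bins: np.ndarray, nfft: int,
              hop: int) -> np.ndarray:
    """Sum over band bins of |STFT| with window ``w`` and the given hop.

    Equivalent to framing x, windowing and FFT-ing, but computed as one
    complex correlation per band bin, which is cheap for narrow bands even
    at hop 1.
    """
    nw = w.size
    total = np.zeros(x.size - nw + 1)
    ns = np.arange(nw)
    for k in bins:
        kern = (w * np.exp(-2j * np.pi * k * ns / nfft))[::-1]
        total += np.abs(fftconvolve(x, kern, mode="valid"))
    return total[::hop]


def stft_bands(time: np.ndarray, vel_lcs: np.ndarray, sample_rate: float,
               cfg: Optional[StftConfig] = None) -> Optional[SpectralSummary]:
    """Band-magnitude summary of the sideways and vertical velocity of one
    contiguous block; None (with a warning) if the block is shorter than one
    window."""
    cfg = cfg or StftConfig()
    time = np.asarray(time, dtype=float)
    if time.size < cfg.window:
        warnings.warn(
            f"block of {time.size} samples is shorter than the "
            f"{cfg.window}-sample STFT window; no spectral gating",
            stacklevel=2)
        return None
    w = get_window("hann", cfg.window, fftbins=True)
    side_bins = _band_bins(sample_rate, cfg.nfft, cfg.band_side)
    vert_bins = _band_bins(sample_rate, cfg.nfft, cfg.band_vert)
    band_side = _band_sum(vel_lcs[:, 1], w, side_bins, cfg.nfft, cfg.hop)
    band_vert = _band_sum(vel_lcs[:, 2], w, vert_bins, cfg.nfft, cfg.hop)
    starts = np.arange(0, time.size - cfg.window + 1, cfg.hop)
    centers = time[0] + (starts + (cfg.window - 1) / 2.0) / sample_rate
    return SpectralSummary(times=centers, band_side=band_side,
                           band_vert=band_vert)


def gate_tuck(summary: SpectralSummary, thr: Thresholds,
              block_span: Optional[Tuple[float, float]] = None
              ) -> List[Tuple[float, float]]:
    """Time intervals classified as Tuck: frames with band_side strictly
    below ``T_tuck``.

    If ``block_span`` is given and the first/last frame is Tuck, the
    interval is extended to the block edge (the window centre cannot reach
    closer than half a window to the edges).
    """
    mask = summary.band_side < thr.t_tuck
    intervals: List[Tuple[float, float]] = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            t0, t1 = summary.times[i], summary.times[j]
            if block_span is not None:
                if i == 0:
                    t0 = block_span[0]
                if j == n - 1:
                    t1 = block_span[1]
            intervals.append((float(t0), float(t1)))
            i = j + 1
        else:
            i += 1
    return intervals


def band_means_for_cycle(summary: Optional[SpectralSummary], t0: float,
                         t1: float) -> Tuple[float, float]:
    """Mean band sums over the frames whose centres fall inside [t0, t1);
    nearest frame if none do (short cycles near block edges)."""
    if summary is None:
        return np.nan, np.nan
    sel = (summary.times >= t0) & (summary.times < t1)
    if not np.any(sel):
        idx = int(np.argmin(np.abs(summary.times - 0.5 * (t0 + t1))))
        sel = np.zeros(summary.times.size, dtype=bool)
        sel[idx] = True
    return (float(summary.band_side[sel].mean()),
            float(summary.band_vert[sel].mean()))


# ---------------------------------------------------------------------------
# neural network classifier
# ---------------------------------------------------------------------------

@dataclass
class NNCModel:
    """Feed-forward network (26 inputs, one 15-unit tanh hidden layer,
    softmax output over the technique classes), with explicit weights so the
    model serializes to plain JSON.

    With two classes the trainer produces a single logistic output; the
    forward pass handles both conventions and always returns a probability
    vector over ``classes`` summing to 1.
    """

    w1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray
    w2: np.ndarray  # (n_hidden, n_out)
    b2: np.ndarray
    classes: List[str]
    metadata: Dict = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        h = np.tanh(x @ self.w1 + self.b1)
        z = h @ self.w2 + self.b2
        if z.shape[1] == 1:  # binary: single logistic unit
            p1 = 1.0 / (1.0 + np.exp(-z[:, 0]))
            probs = np.column_stack([1.0 - p1, p1])
        else:
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs = e / e.sum(axis=1, keepdims=True)
        return probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(x)
        return np.asarray(self.classes)[np.argmax(probs, axis=1)]

    # -- JSON (de)serialization ---------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "architecture": [self.w1.shape[0], self.w1.shape[1],
                             self.w2.shape[1]],
            "classes": list(self.classes),
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2.tolist(),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NNCModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(w1=np.asarray(payload["w1"]), b1=np.asarray(payload["b1"]),
                   w2=np.asarray(payload["w2"]), b2=np.asarray(payload["b2"]),
                   classes=list(payload["classes"]),
                   metadata=payload.get("metadata", {}))


def train_nnc(features: np.ndarray, labels: Sequence[str], seed: int = 0,
              validation_fraction: float = 0.2, alpha: float = 1e-4,
              hidden: int = 15, max_iter: int = 3000) -> NNCModel:
    """Train the technique network on per-cycle feature vectors.

    A stratified random ``validation_fraction`` of the cycles is held out;
    the network (tanh hidden layer, L2 weight decay ``alpha`` standing in
    for Bayesian regularization) is fitted on the remainder with a
    deterministic full-batch quasi-Newton optimizer. Train and validation
    accuracies are reported in the model metadata.
    """
    from sklearn.model_selection import train_test_split
    from sklearn.neural_network import MLPClassifier

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes to train")
    low = classes[counts < 2]
    if low.size:
        raise ValueError(f"classes with fewer than 2 examples: {list(low)}")

    x_tr, x_va, y_tr, y_va = train_test_split(
        features, labels, test_size=validation_fraction, random_state=seed,
        stratify=labels)
    net = MLPClassifier(hidden_layer_sizes=(hidden,), activation="tanh",
                        solver="lbfgs", alpha=alpha, max_iter=max_iter,
                        random_state=seed, tol=1e-9)
    net.fit(x_tr, y_tr)
    model = NNCModel(
        w1=net.coefs_[0], b1=net.intercepts_[0],
        w2=net.coefs_[1], b2=net.intercepts_[1],
        classes=[str(c) for c in net.classes_],
        metadata={
            "seed": int(seed),
            "validation_fraction": float(validation_fraction),
            "alpha": float(alpha),
            "n_iter": int(net.n_iter_),
            "n_train": int(len(y_tr)), "n_validation": int(len(y_va)),
        })
    model.metadata["train_accuracy"] = float(
        np.mean(model.predict(x_tr) == y_tr))
    model.metadata["validation_accuracy"] = float(
        np.mean(model.predict(x_va) == y_va))
    return model


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------

def classify_cycle(record: CycleRecord, feature: Optional[np.ndarray],
                   thr: Thresholds,
                   model: Optional[NNCModel] = None) -> str:
    """Label one detected cycle (Tuck periods are gated out upstream).

    Precedence: Turn (heading rate above ``T_turn``) over G5 (vertical band
    below ``T_G5``) over the NNC with left/right merging. Without a trained
    model only the hard-rule labels are possible; other cycles come back
    ``unclassified``.
    """
    if record.heading_rate > thr.t_turn:
        return "Turn"
    if np.isfinite(record.band_vert) and record.band_vert < thr.t_g5:
        return "G5"
    if model is None or feature is None:
        return "unclassified"
    raw = str(model.predict(feature[None, :])[0])
    return MERGE_MAP.get(raw, raw)


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


@dataclass
class TimelineResult:
    records: List[CycleRecord]
    features: np.ndarray
    tuck_intervals: List[Tuple[float, float]]
    excluded_intervals: List[Tuple[float, float]]
    report: Dict

    def cycle_frame(self):
        return records_to_frame(self.records)


def classify_timeline(traj: TrajectorySeries,
                      model: Optional[NNCModel] = None,
                      config: Optional[PipelineConfig] = None
                      ) -> TimelineResult:
    """Run the full pipeline on a raw trajectory.

    Float-ambiguity periods are excluded; Tuck is gated on time intervals
    before cycle detection (cycles overlapping a Tuck interval by more than
    half their duration are suppressed); the remaining cycles are measured
    and labelled through the decision tree.
    """
    cfg = config or PipelineConfig()
    thr = cfg.thresholds
    n_feat = 2 * (2 * cfg.max_lag + 1)
    try:
        smooth = smooth_spline(traj, cfg.noise_sd)
        origin = lowpass_trajectory(smooth, cutoff=cfg.cutoff_hz,
                                    order=cfg.butter_order)
    except ValueError:
        # no usable fixed-ambiguity block: everything is excluded
        span = ([(float(traj.time[0]), float(traj.time[-1]))]
                if traj.n else [])
        return TimelineResult(
            records=[], features=np.empty((0, n_feat)), tuck_intervals=[],
            excluded_intervals=span,
            report={"n_cycles": 0, "class_counts": {},
                    "n_tuck_intervals": 0, "fraction_excluded": 1.0})
    lcs = build_lcs(smooth, origin, min_speed=cfg.min_speed)
    # keep only the samples retained by the low-pass stage
    smooth_kept = smooth
    if smooth.n != lcs.n:
        keep = np.isin(np.round(smooth.time * 1e6).astype(np.int64),
                       np.round(lcs.time * 1e6).astype(np.int64))
        smooth_kept = smooth.slice(np.flatnonzero(keep))

    all_records: List[CycleRecord] = []
    all_features: List[np.ndarray] = []
    tuck_all: List[Tuple[float, float]] = []

    series_for_blocks = TrajectorySeries(lcs.time, smooth_kept.pos,
                                         np.ones(lcs.n, dtype=bool),
                                         vel=smooth_kept.vel)
    for sl in contiguous_blocks(series_for_blocks, min_len=2, use_fix=False):
        t = lcs.time[sl]
        summary = None
        if t.size >= cfg.stft.window:
            summary = stft_bands(t, lcs.vel_lcs[sl], cfg.sample_rate,
                                 cfg.stft)
        tucks = (gate_tuck(summary, thr, block_span=(t[0], t[-1]))
                 if summary is not None else [])
        tuck_all.extend(tucks)

        boundaries = detect_cycles(t, lcs.vel_lcs[sl, 1],
                                   prominence=cfg.prominence,
                                   min_separation=cfg.min_separation,
                                   valid=lcs.valid[sl])
        records = measure_cycles(boundaries, smooth_kept, lcs)
        # the low-pass origin is unreliable within a settling length of the
        # block edges; cycles reaching into that region are discarded
        guard = cfg.edge_guard_periods / cfg.cutoff_hz
        records = [r for r in records
                   if r.t_start >= t[0] + guard and r.t_end <= t[-1] - guard]
        # suppress cycles that are mostly inside a Tuck interval
        records = [r for r in records
                   if not any(_overlap(r.t_start, r.t_end, a, b)
                              > 0.5 * r.duration for a, b in tucks)]
        for r in records:
            r.band_side, r.band_vert = band_means_for_cycle(
                summary, r.t_start, r.t_end)
        feats, kept = features_for_cycles(lcs, records,
                                          n_points=cfg.n_resample,
                                          max_lag=cfg.max_lag)
        records = [records[i] for i in kept]
        for rec, feat in zip(records, feats):
            rec.label = classify_cycle(rec, feat, thr, model)
        all_records.extend(records)
        all_features.extend(feats)

    # excluded (float or dropped) time: complement of retained samples
    excluded = _complement_intervals(traj.time, lcs.time)

    features = (np.vstack(all_features) if all_features
                else np.empty((0, n_feat)))
    counts: Dict[str, int] = {}
    for r in all_records:
        counts[r.label] = counts.get(r.label, 0) + 1
    report = {
        "n_cycles": len(all_records),
        "class_counts": counts,
        "n_tuck_intervals": len(tuck_all),
        "fraction_excluded": float(1.0 - lcs.n / traj.n) if traj.n else 0.0,
    }
    return TimelineResult(records=all_records, features=features,
                          tuck_intervals=tuck_all,
                          excluded_intervals=excluded, report=report)


def _complement_intervals(full_time: np.ndarray,
                          kept_time: np.ndarray) -> List[Tuple[float, float]]:
    kept = np.isin(np.round(full_time * 1e6).astype(np.int64),
                   np.round(kept_time * 1e6).astype(np.int64))
    out: List[Tuple[float, float]] = []
    i = 0
    n = full_time.size
    while i < n:
        if not kept[i]:
            j = i
            while j + 1 < n and not kept[j + 1]:
                j += 1
            out.append((float(full_time[i]), float(full_time[j])))
            i = j + 1
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# synthetic training corpus
# ---------------------------------------------------------------------------

def build_feature_corpus(class_counts: Optional[Dict[str, int]] = None,
                         seed: int = 0,
                         config: Optional[PipelineConfig] = None
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Labelled feature corpus from synthetic treadmill-style trials.

    The default class counts mirror the composition of the treadmill
    training set (45 G2R, 120 G2L, 165 G3, 120 G4R, 60 G4L = 510 cycles).
    Trials vary cycle frequency, speed and amplitude scale per class; 30 mm
    white noise is added; features come from the standard pipeline.
    """
    from .synthgen import TEMPLATES, add_noise, generate_trial
    from dataclasses import replace as _replace

    cfg = config or PipelineConfig()
    counts = dict(class_counts or
                  {"G2R": 45, "G2L": 120, "G3": 165, "G4R": 120, "G4L": 60})
    rng = np.random.default_rng(seed)
    feats: List[np.ndarray] = []
    labs: List[str] = []
    for label in sorted(counts):
        needed = counts[label]
        base = TEMPLATES[label]
        while needed > 0:
            f = float(rng.uniform(0.6, 0.9))
            speed = float(rng.uniform(3.0, 5.0))
            scale = float(rng.uniform(0.85, 1.15))
            tpl = _replace(
                base, cycle_frequency=f,
                sideways_amplitude=base.sideways_amplitude * scale,
                vertical_amplitude=base.vertical_amplitude * scale,
                foreaft_amplitude=base.foreaft_amplitude * scale)
            guard = cfg.edge_guard_periods / cfg.cutoff_hz
            n_cycles = min(max(needed, 8), 28)
            duration = (n_cycles + 2) / f + 2 * guard
            sub = int(rng.integers(0, 2**31 - 1))
            traj, _ = generate_trial(tpl, duration, speed, seed=sub,
                                     sample_rate=cfg.sample_rate)
            noisy = add_noise(traj, cfg.noise_sd, seed=sub)
            smooth = smooth_spline(noisy, cfg.noise_sd)
            origin = lowpass_trajectory(smooth, cfg.cutoff_hz,
                                        cfg.butter_order)
            lcs = build_lcs(smooth, origin, min_speed=cfg.min_speed)
            bnds = detect_cycles(lcs.time, lcs.vel_lcs[:, 1],
                                 cfg.prominence, cfg.min_separation,
                                 valid=lcs.valid)
            recs = measure_cycles(bnds, smooth, lcs)
            guard = cfg.edge_guard_periods / cfg.cutoff_hz
            recs = [r for r in recs if r.t_start >= lcs.time[0] + guard
                    and r.t_end <= lcs.time[-1] - guard]
            mat, kept = features_for_cycles(lcs, recs,
                                            n_points=cfg.n_resample,
                                            max_lag=cfg.max_lag)
            take = min(needed, mat.shape[0])
            feats.append(mat[:take])
            labs.extend([label] * take)
            needed -= take
    return np.vstack(feats), np.asarray(labs)


__all__ = [
    "SpectralSummary", "NNCModel", "MERGE_MAP", "stft_bands", "gate_tuck",
    "band_means_for_cycle", "classify_cycle", "train_nnc",
    "classify_timeline", "TimelineResult", "build_feature_corpus",
]
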