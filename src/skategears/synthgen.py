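"""Synthetic head-trajectory generator with known ground truth.

Emulates the two recording situations the pipeline is designed for:

* treadmill-style trials — constant speed and incline, a single technique,
  15+ movement cycles, to which 30 mm white position noise is added to mimic
  carrier-phase differential GNSS of a head-mounted antenna at 50 Hz;
* field-style courses — concatenated segments with turning (constant heading
  rate), downhill tuck phases, poles-free G5 stretches, and windows of lost
  ambiguity resolution flagged ``float``.

Each technique is modelled as one or two sinusoidal harmonics per local axis
riding on a straight (or turning) progression. Sinusoids are deliberately
simple: they reproduce the phase relations between fore-aft, sideways and
vertical head motion that the cross-correlation features encode, while every
ground-truth quantity (cycle events, heading change, noise energy) stays
analytically checkable. Amplitudes are illustrative calibration constants,
not measured values; they are chosen so that the spectral band sums of the
G2-G4 templates clear the published decision thresholds (40 and 100 m/s)
while Tuck and G5 fall below them, mirroring the separation observed in real
recordings.

The sideways oscillation carries a fixed -pi/2 phase so that the true cycle
events (sideways-velocity maxima) fall strictly inside the sampled interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .containers import FIXED, FLOAT, GroundTruth, TrajectorySeries

_UP = np.array([0.0, 0.0, 1.0])
_SIDE_PHASE = -math.pi / 2.0  # sideways = A*sin(2*pi*f*t + _SIDE_PHASE)


@dataclass(frozen=True)
class TechniqueTemplate:
    """Per-technique oscillation model of the head about its mean path.

    ``sideways_sign`` encodes the left/right variant: mirroring negates the
    sideways component. ``vertical_harmonic_ratio`` is the relative amplitude
    of a vertical component at twice the cycle frequency (nonzero for G3,
    which has two pole pushes per movement cycle).
    """

    label: str
    sideways_amplitude: float   # m
    vertical_amplitude: float   # m
    foreaft_amplitude: float    # m
    phase_vertical_vs_sideways: float = 0.0  # rad
    phase_foreaft_vs_sideways: float = 0.0   # rad
    vertical_harmonic_ratio: float = 0.0
    cycle_frequency: float = 0.7  # Hz
    sideways_sign: int = 1

    def __post_init__(self) -> None:
        if min(self.sideways_amplitude, self.vertical_amplitude,
               self.foreaft_amplitude) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.cycle_frequency <= 0:
            raise ValueError("cycle_frequency must be positive")
        if self.sideways_sign not in (-1, 1):
            raise ValueError("sideways_sign must be +1 or -1")

    # local-frame oscillation components ------------------------------------

    def oscillation(self, t: np.ndarray) -> np.ndarray:
        """(n, 3) array of (fore-aft, sideways, vertical) offsets, metres."""
        t = np.asarray(t, dtype=float)
        th = 2.0 * math.pi * self.cycle_frequency * t + _SIDE_PHASE
        side = self.sideways_sign * self.sideways_amplitude * np.sin(th)
        vert = self.vertical_amplitude * (
            np.sin(th + self.phase_vertical_vs_sideways)
            + self.vertical_harmonic_ratio
            * np.sin(2.0 * th + 2.0 * self.phase_vertical_vs_sideways)
        )
        fore = self.foreaft_amplitude * np.sin(th + self.phase_foreaft_vs_sideways)
        return np.column_stack([fore, side, vert])

    def event_times(self, duration: float) -> np.ndarray:
        """Analytic sideways-velocity maxima in [0, duration).

        Empty for techniques without a usable sideways oscillation (Tuck, or
        zero amplitude).
        """
        if self.sideways_amplitude == 0.0 or self.label == "Tuck":
            return np.empty(0)
        f = self.cycle_frequency
        # d(side)/dt ~ sign * cos(2*pi*f*t - pi/2); maxima where the cosine
        # equals sign: t = (k + 1/4)/f for the left variant, (k + 3/4)/f for
        # the mirrored one.
        frac = 0.25 if self.sideways_sign > 0 else 0.75
        k_max = int(math.floor(duration * f - frac))
        if duration * f - frac == k_max:  # half-open interval
            k_max -= 1
        if k_max < 0:
            return np.empty(0)
        return (np.arange(k_max + 1) + frac) / f

    def mirror(self) -> "TechniqueTemplate":
        """Left/right mirrored template (sideways component negated)."""
        mapping = {"G2L": "G2R", "G2R": "G2L", "G4L": "G4R", "G4R": "G4L"}
        return replace(self, label=mapping.get(self.label, self.label),
                       sideways_sign=-self.sideways_sign)


def default_templates() -> dict:
    """Illustrative technique templates, keyed by label.

    Amplitudes and phases are calibration constants (see module docstring),
    chosen so the five NNC classes have distinct cross-correlation waveforms
    and the hard decision rules route G2-G4 / G5 / Tuck as in the field data.
    """
    g2l = TechniqueTemplate(
        label="G2L", sideways_amplitude=0.20, vertical_amplitude=0.18,
        foreaft_amplitude=0.05, phase_vertical_vs_sideways=-1.0,
        phase_foreaft_vs_sideways=0.6, cycle_frequency=0.7)
    g4l = TechniqueTemplate(
        label="G4L", sideways_amplitude=0.20, vertical_amplitude=0.17,
        foreaft_amplitude=0.06, phase_vertical_vs_sideways=1.2,
        phase_foreaft_vs_sideways=-0.9, cycle_frequency=0.8)
    g3 = TechniqueTemplate(
        label="G3", sideways_amplitude=0.20, vertical_amplitude=0.12,
        foreaft_amplitude=0.05, phase_vertical_vs_sideways=-0.5,
        phase_foreaft_vs_sideways=2.0, vertical_harmonic_ratio=1.5,
        cycle_frequency=0.75)
    g5 = TechniqueTemplate(
        label="G5", sideways_amplitude=0.22, vertical_amplitude=0.008,
        foreaft_amplitude=0.04, phase_vertical_vs_sideways=0.4,
        phase_foreaft_vs_sideways=-0.5, cycle_frequency=0.8)
    tuck = TechniqueTemplate(
        label="Tuck", sideways_amplitude=0.005, vertical_amplitude=0.005,
        foreaft_amplitude=0.0, cycle_frequency=0.7)
    # Turning is skated with a G3-like coordination; the truth label differs.
    turn = replace(g3, label="Turn")
    return {"G2L": g2l, "G2R": g2l.mirror(), "G3": g3,
            "G4L": g4l, "G4R": g4l.mirror(), "G5": g5,
            "Tuck": tuck, "Turn": turn}


TEMPLATES = default_templates()


# ---------------------------------------------------------------------------
# treadmill-style trials
# ---------------------------------------------------------------------------

def generate_trial(
    template: TechniqueTemplate,
    duration: float,
    speed: float,
    seed: Optional[int] = None,
    sample_rate: float = 50.0,
    pole_offset: float = 0.15,
    pole_jitter_sd: float = 0.020,
) -> Tuple[TrajectorySeries, GroundTruth]:
    """Noiseless straight-line trial: progression at ``speed`` due north plus
    the template oscillations.

    Ground-truth cycle events sit at the analytic sideways-velocity maxima;
    pole-plant criterion events are offset by ``pole_offset`` seconds plus
    Gaussian jitter (SD ``pole_jitter_sd``), emulating the independent
    criterion measurement used to assess cycle-averaging behaviour.
    """
    f = template.cycle_frequency
    if template.sideways_amplitude > 0 and duration * f < 3:
        raise ValueError("duration must cover at least 3 full cycles")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    # heading due north: e_ski=(0,1,0), e_side=(1,0,0) (east), e_vert=up
    osc = template.oscillation(t)
    base = np.column_stack([np.zeros(n), speed * t, np.zeros(n)])
    pos = base.copy()
    pos[:, 1] += osc[:, 0]   # fore-aft along travel
    pos[:, 0] += osc[:, 1]   # sideways = east
    pos[:, 2] += osc[:, 2]   # vertical
    traj = TrajectorySeries(t, pos, np.ones(n, dtype=bool))

    events = template.event_times(duration)
    labels = [template.label] * max(events.size - 1, 0)
    rng = np.random.default_rng(seed)
    if events.size:
        plants = events + pole_offset + rng.normal(0.0, pole_jitter_sd,
                                                   events.size)
    else:
        plants = np.empty(0)
    intervals = []
    if template.label == "Tuck":
        intervals.append((0.0, float(duration), "Tuck"))
    truth = GroundTruth(cycle_events=events, labels=labels,
                        pole_plants=plants, intervals=intervals,
                        com_positions=base)
    return traj, truth


def add_noise(traj: TrajectorySeries, sd: float,
              seed: Optional[int] = None) -> TrajectorySeries:
    """Add independent zero-mean Gaussian noise per axis per sample."""
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return traj.copy()
    rng = np.random.default_rng(seed)
    noisy = traj.pos + rng.normal(0.0, sd, traj.pos.shape)
    return TrajectorySeries(traj.time.copy(), noisy, traj.fix.copy())


# ---------------------------------------------------------------------------
# field-style courses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CourseSegment:
    duration: float          # s
    label: str               # technique / truth label, key into templates
    speed: float             # m/s
    heading_rate: float = 0.0  # deg/s, positive clockwise (east of north)
    incline: float = 0.0       # deg, positive uphill

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.speed < 0:
            raise ValueError("segment speed must be non-negative")


@dataclass
class CoursePlan:
    segments: List[CourseSegment]
    sample_rate: float = 50.0
    noise_sd: float = 0.030
    outage_windows: List[Tuple[float, float]] = field(default_factory=list)
    templates: dict = field(default_factory=default_templates)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("plan needs at least one segment")
        windows = sorted(self.outage_windows)
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            if b0 < a1:
                raise ValueError("overlapping outage windows")
        for a0, a1 in windows:
            if a1 <= a0:
                raise ValueError("outage window must have positive length")
        for seg in self.segments:
            tpl = self.templates[seg.label]
            if self.sample_rate <= 2 * 2 * tpl.cycle_frequency:
                raise ValueError("sample_rate below Nyquist for template")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @classmethod
    def from_dict(cls, d: dict) -> "CoursePlan":
        segs = [CourseSegment(
            duration=float(s["duration"]), label=str(s["label"]),
            speed=float(s["speed"]),
            heading_rate=float(s.get("heading_rate", 0.0)),
            incline=float(s.get("incline", 0.0)),
        ) for s in d["segments"]]
        return cls(segments=segs,
                   sample_rate=float(d.get("sample_rate", 50.0)),
                   noise_sd=float(d.get("noise_sd", 0.030)),
                   outage_windows=[tuple(map(float, w))
                                   for w in d.get("outage_windows", [])])


def _segment_base(p0: np.ndarray, psi0: float, seg: CourseSegment,
                  tau: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Analytic mean path within a segment.

    Returns positions (n, 3) and headings (rad) at local times ``tau``.
    Heading psi is the azimuth east of north; horizontal direction is
    (sin psi, cos psi).
    """
    omega = math.radians(seg.heading_rate)
    v_h = seg.speed * math.cos(math.radians(seg.incline))
    v_u = seg.speed * math.sin(math.radians(seg.incline))
    psi = psi0 + omega * tau
    if abs(omega) > 1e-12:
        east = p0[0] + v_h / omega * (np.cos(psi0) - np.cos(psi))
        north = p0[1] + v_h / omega * (np.sin(psi) - np.sin(psi0))
    else:
        east = p0[0] + v_h * np.sin(psi0) * tau
        north = p0[1] + v_h * np.cos(psi0) * tau
    up = p0[2] + v_u * tau
    return np.column_stack([east, north, up]), psi


def generate_course(plan: CoursePlan,
                    seed: Optional[int] = None
                    ) -> Tuple[TrajectorySeries, GroundTruth]:
    """Noiseless concatenated-course trajectory with per-segment truth.

    Position is C0-continuous across segment joins (each segment's
    oscillation is offset to start at zero); heading integrates the segment
    heading rate; samples inside outage windows are flagged ``float``.
    Callers add measurement noise with :func:`add_noise` (``plan.noise_sd``).
    """
    fs = plan.sample_rate
    n = int(round(plan.total_duration * fs))
    t = np.arange(n) / fs
    pos = np.empty((n, 3))
    base_all = np.empty((n, 3))

    rng = np.random.default_rng(seed)
    events: List[float] = []
    labels: List[str] = []
    intervals: List[Tuple[float, float, str]] = []
    seg_bounds: List[Tuple[float, float, str]] = []

    p0 = np.zeros(3)
    psi0 = 0.0
    t0 = 0.0
    for seg in plan.segments:
        tpl = plan.templates[seg.label]
        t1 = t0 + seg.duration
        sl = (t >= t0 - 1e-12) & (t < t1 - 1e-12)
        tau = t[sl] - t0
        base, psi = _segment_base(p0, psi0, seg, tau)
        osc = tpl.oscillation(tau)
        osc = osc - tpl.oscillation(np.array([0.0]))  # C0 continuity at join
        e_ski = np.column_stack([np.sin(psi), np.cos(psi), np.zeros(psi.size)])
        e_side = np.column_stack([np.cos(psi), -np.sin(psi), np.zeros(psi.size)])
        pos[sl] = (base + osc[:, [0]] * e_ski + osc[:, [1]] * e_side
                   + osc[:, [2]] * _UP)
        base_all[sl] = base

        seg_events = tpl.event_times(seg.duration) + t0
        events.extend(seg_events.tolist())
        if tpl.label == "Tuck" or tpl.sideways_amplitude == 0:
            intervals.append((t0, t1, seg.label))
        seg_bounds.append((t0, t1, seg.label))

        # advance state to the segment end (analytic, not last sample)
        end_base, end_psi = _segment_base(p0, psi0, seg,
                                          np.array([seg.duration]))
        p0 = end_base[0]
        psi0 = float(end_psi[0])
        t0 = t1

    events_arr = np.asarray(events)
    if events_arr.size:
        if np.any(np.diff(events_arr) <= 0):
            raise AssertionError("ground-truth events not increasing")
        def _segment_of(x: float) -> int:
            for i, (a, b, _lab) in enumerate(seg_bounds):
                if a - 1e-9 <= x < b - 1e-9:
                    return i
            return len(seg_bounds) - 1

        for e0, e1 in zip(events_arr[:-1], events_arr[1:]):
            i0, i1 = _segment_of(e0), _segment_of(e1)
            # an interval whose events fall in different segments is not a
            # technique cycle of either segment
            labels.append(seg_bounds[i0][2] if i0 == i1 else "transition")

    fix = np.ones(n, dtype=bool)
    for (a, b) in plan.outage_windows:
        fix[(t >= a - 1e-12) & (t < b - 1e-12)] = False

    plants = (events_arr + 0.15 + rng.normal(0.0, 0.020, events_arr.size)
              if events_arr.size else np.empty(0))
    traj = TrajectorySeries(t, pos, fix)
    truth = GroundTruth(cycle_events=events_arr, labels=labels,
                        pole_plants=plants, intervals=intervals,
                        com_positions=base_all)
    return traj, truth


__all__ = [
    "TechniqueTemplate", "CourseSegment", "CoursePlan", "TEMPLATES",
    "default_templates", "generate_trial", "generate_course", "add_noise",
]
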