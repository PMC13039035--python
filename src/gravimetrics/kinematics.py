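"""Movement segmentation, center-of-mass computation, and gait metrics.

Movement onset/offset are detected either on displacement (5% / 95% of the
total movement amplitude, the amplitude being taken from steady phases before
and after the movement) or on velocity (5% of peak velocity). The whole-body
center of mass comes from a seven-segment rigid-body model (Trunk, Thigh,
Shank, Foot, Upper Arm, Forearm, Hand) with anthropometric mass/length/CoM
fractions frozen in :data:`WINTER_TABLE`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .io_signals import MarkerTrajectory, SampledSignal, zero_phase_filter

__all__ = [
    "MovementBounds",
    "AnthropometricTable",
    "WINTER_TABLE",
    "ComTrajectory",
    "GaitMetrics",
    "detect_bounds_displacement",
    "detect_bounds_velocity",
    "movement_amplitude",
    "compute_com",
    "gait_metrics",
]

# steady-phase lengths used to estimate movement amplitude, seconds
STEADY_S = {"fast": 0.200, "slow": 0.500}
# a crossing must hold for this long to count as onset (suppresses noise)
ONSET_HOLD_S = 0.025


@dataclass(frozen=True)
class MovementBounds:
    onset_idx: int
    offset_idx: int
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        if not self.onset_idx < self.offset_idx:
            raise ValueError("movement onset must precede offset")

    @property
    def onset_s(self) -> float:
        return self.t0 + self.onset_idx / self.rate

    @property
    def offset_s(self) -> float:
        return self.t0 + self.offset_idx / self.rate

    @property
    def duration_s(self) -> float:
        return (self.offset_idx - self.onset_idx) / self.rate


@dataclass(frozen=True)
class AnthropometricTable:
    """Per-segment mass fraction (of body mass), length fraction (of height)
    and CoM position (fraction of segment length from the proximal end)."""

    mass_fraction: Mapping[str, float]
    length_fraction: Mapping[str, float]
    com_fraction: Mapping[str, float]

    def __post_init__(self):
        for name, table in (
            ("mass_fraction", self.mass_fraction),
            ("length_fraction", self.length_fraction),
            ("com_fraction", self.com_fraction),
        ):
            for seg, v in table.items():
                if not 0.0 < v < 1.0:
                    raise ValueError(f"{name}[{seg!r}] = {v} outside (0, 1)")

    @property
    def segments(self) -> tuple[str, ...]:
        return tuple(self.mass_fraction)


# Classic cadaver-study anthropometric fractions (Winter-style tables).
# Mass fractions are the BILATERAL totals for paired segments (2x unilateral)
# so the seven segments partition the modelled body; the CoM computation
# renormalizes them to sum to one (head/neck mass is not modelled separately,
# the trunk segment absorbs it geometrically).
WINTER_TABLE = AnthropometricTable(
    mass_fraction={
        "Trunk": 0.497,
        "Thigh": 0.200,     # 2 x 0.100
        "Shank": 0.093,     # 2 x 0.0465
        "Foot": 0.029,      # 2 x 0.0145
        "UpperArm": 0.056,  # 2 x 0.028
        "Forearm": 0.032,   # 2 x 0.016
        "Hand": 0.012,      # 2 x 0.006
    },
    length_fraction={
        "Trunk": 0.288,
        "Thigh": 0.245,
        "Shank": 0.246,
        "Foot": 0.152,
        "UpperArm": 0.186,
        "Forearm": 0.146,
        "Hand": 0.108,
    },
    com_fraction={
        "Trunk": 0.500,
        "Thigh": 0.433,
        "Shank": 0.433,
        "Foot": 0.500,
        "UpperArm": 0.436,
        "Forearm": 0.430,
        "Hand": 0.506,
    },
)


@dataclass(frozen=True)
class ComTrajectory:
    xyz: SampledSignal
    displacement_norm: float
    peak_velocity: float

    def __post_init__(self):
        if self.displacement_norm < 0 or self.peak_velocity < 0:
            raise ValueError("CoM summary metrics must be nonnegative")


@dataclass(frozen=True)
class GaitMetrics:
    feet_spacing: float
    step_rate: float
    step_length_mean: float
    step_length_sd: float
    n_steps: int


# ---------------------------------------------------------------------------
# movement segmentation
# ---------------------------------------------------------------------------

def _displacement_profile(values: np.ndarray, speed: str, n_pre: int) -> np.ndarray:
    """Scalar displacement from the pre-movement steady position.

    Fast movements use the vertical (Z) axis only; slow movements use the 3-D
    Euclidean distance from the steady start position (more robust on the
    noisier slow traces).
    """
    if values.ndim == 1:
        ref = values[:n_pre].mean()
        return np.abs(values - ref)
    if values.shape[1] != 3:
        raise ValueError("displacement signal must be 1-D or 3-column")
    if speed == "fast":
        z = values[:, 2]
        return np.abs(z - z[:n_pre].mean())
    ref = values[:n_pre].mean(axis=0)
    return np.linalg.norm(values - ref, axis=1)


def detect_bounds_displacement(
    disp: SampledSignal,
    speed: str,
    noise_floor: float = 1e-3,
) -> MovementBounds:
    """Onset/offset at 5% / 95% of the total movement amplitude.

    Amplitude is the difference between the mean of the post-movement steady
    phase and the mean of the pre-movement steady phase (200 ms for fast,
    500 ms for slow movements). Onset is the first sample rising above 5% of
    that amplitude and staying above it for at least 25 ms; offset is the
    first subsequent sample above 95%.
    """
    if speed not in STEADY_S:
        raise ValueError("speed must be 'slow' or 'fast'")
    n_pre = int(round(STEADY_S[speed] * disp.rate))
    if len(disp) < 2 * n_pre + 2:
        raise ValueError("trace shorter than two steady phases")
    d = _displacement_profile(disp.values, speed, n_pre)
    amp = abs(d[-n_pre:].mean() - d[:n_pre].mean())
    if amp <= noise_floor:
        raise ValueError("no movement detected (amplitude below noise floor)")
    frac = (d - d[:n_pre].mean()) / amp

    hold = max(1, int(round(ONSET_HOLD_S * disp.rate)))
    above = frac > 0.05
    onset = None
    for i in np.flatnonzero(above):
        if above[i : i + hold].all():
            onset = int(i)
            break
    if onset is None:
        raise ValueError("no movement detected (no sustained 5% crossing)")
    rest = np.flatnonzero(frac[onset:] > 0.95)
    if rest.size == 0:
        raise ValueError("no movement detected (no 95% crossing after onset)")
    offset = onset + int(rest[0])
    if offset <= onset:
        raise ValueError("degenerate movement (onset == offset)")
    return MovementBounds(onset, offset, disp.rate, disp.t0)


def detect_bounds_velocity(vel: SampledSignal, noise_floor: float = 1e-6) -> MovementBounds:
    """Onset/offset where the velocity magnitude crosses 5% of its peak.

    Ties between equal peaks are broken toward the earlier peak. Onset is one
    sample after the last sub-threshold sample before the peak; offset is one
    sample before the first sub-threshold sample after the peak.
    """
    v = np.abs(np.asarray(vel.values, dtype=float))
    if v.ndim != 1:
        v = np.linalg.norm(vel.values, axis=1)
    vmax = v.max()
    if vmax <= noise_floor:
        raise ValueError("no movement detected (zero velocity)")
    peak = int(np.argmax(v))  # argmax takes the first of equal peaks
    thr = 0.05 * vmax
    below_pre = np.flatnonzero(v[:peak] < thr)
    onset = int(below_pre[-1]) + 1 if below_pre.size else 0
    below_post = np.flatnonzero(v[peak:] < thr)
    offset = peak + int(below_post[0]) - 1 if below_post.size else len(v) - 1
    return MovementBounds(onset, offset, vel.rate, vel.t0)


def movement_amplitude(disp: SampledSignal, speed: str) -> float:
    """Movement amplitude from the pre/post steady phases.

    Fast: |mean(post Z) - mean(pre Z)|. Slow: Euclidean distance between the
    3-D pre and post steady-phase mean positions.
    """
    if speed not in STEADY_S:
        raise ValueError("speed must be 'slow' or 'fast'")
    n = int(round(STEADY_S[speed] * disp.rate))
    if len(disp) < 2 * n + 2:
        raise ValueError("trace shorter than two steady phases")
    v = disp.values
    if v.ndim == 1:
        return float(abs(v[-n:].mean() - v[:n].mean()))
    if speed == "fast":
        return float(abs(v[-n:, 2].mean() - v[:n, 2].mean()))
    return float(np.linalg.norm(v[-n:].mean(axis=0) - v[:n].mean(axis=0)))


# ---------------------------------------------------------------------------
# center of mass
# ---------------------------------------------------------------------------

def compute_com(
    segments: Mapping[str, tuple[np.ndarray, np.ndarray]],
    table: AnthropometricTable = WINTER_TABLE,
    height: float = 1.70,
    rate: float = 200.0,
    filter_hz: float | None = 5.0,
) -> ComTrajectory:
    """Mass-weighted seven-segment center of mass.

    ``segments`` maps segment name to ``(proximal, distal)`` endpoint arrays
    of shape (n, 3) in meters (bilateral segments already averaged). Mass
    fractions are renormalized to sum to one so the CoM is a convex
    combination of segment CoMs. Displacement is the start-to-end distance of
    the CoM between the velocity-based movement bounds, normalized by
    ``height``; peak velocity is the maximum CoM speed, differentiated from
    the 5 Hz low-pass-filtered position.
    """
    missing = [s for s in table.segments if s not in segments]
    if missing:
        raise ValueError(f"missing segment(s): {', '.join(missing)}")
    total = sum(table.mass_fraction[s] for s in table.segments)
    com = None
    n = None
    for s in table.segments:
        prox = np.asarray(segments[s][0], dtype=float)
        dist = np.asarray(segments[s][1], dtype=float)
        if prox.shape != dist.shape or prox.ndim != 2 or prox.shape[1] != 3:
            raise ValueError(f"segment {s!r}: endpoints must be (n, 3) arrays")
        if n is None:
            n = prox.shape[0]
        elif prox.shape[0] != n:
            raise ValueError(f"segment {s!r}: inconsistent frame count")
        seg_com = prox + table.com_fraction[s] * (dist - prox)
        w = table.mass_fraction[s] / total
        com = w * seg_com if com is None else com + w * seg_com

    sig = SampledSignal(com, rate=rate)
    if filter_hz is not None and len(sig) > 40:
        sig = zero_phase_filter(sig, "lowpass", filter_hz)
    vel = np.gradient(sig.values, 1.0 / rate, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    try:
        b = detect_bounds_velocity(SampledSignal(speed, rate=rate))
        start, end = b.onset_idx, b.offset_idx
    except ValueError:
        start, end = 0, len(sig) - 1
    disp = float(np.linalg.norm(sig.values[end] - sig.values[start])) / height
    return ComTrajectory(sig, displacement_norm=disp, peak_velocity=float(speed.max()))


# ---------------------------------------------------------------------------
# gait
# ---------------------------------------------------------------------------

def gait_metrics(
    left_foot: MarkerTrajectory,
    right_foot: MarkerTrajectory,
    prominence: float | None = None,
) -> GaitMetrics:
    """Treadmill gait metrics from the two foot markers.

    Feet spacing is the medio-lateral (Y) distance between the mean foot
    positions. Steps are peaks of the right-foot antero-posterior (X)
    excursion; step rate is (n_peaks - 1) / (t_last - t_first) and step
    length mean/sd are the mean/sd of those peaks' prominences.
    """
    ly = left_foot.xyz.values[:, 1]
    ry = right_foot.xyz.values[:, 1]
    spacing = float(abs(ly.mean() - ry.mean()))

    x = right_foot.xyz.values[:, 0]
    if prominence is None:
        prominence = 0.25 * float(np.ptp(x))
    peaks, props = sps.find_peaks(x, prominence=prominence)
    if peaks.size < 2:
        raise ValueError("fewer than 2 step peaks detected")
    t = right_foot.xyz.times
    step_rate = float((peaks.size - 1) / (t[peaks[-1]] - t[peaks[0]]))
    prom = props["prominences"]
    return GaitMetrics(
        feet_spacing=spacing,
        step_rate=step_rate,
        step_length_mean=float(prom.mean()),
        step_length_sd=float(prom.std(ddof=1)) if prom.size > 1 else 0.0,
        n_steps=int(peaks.size),
    )
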