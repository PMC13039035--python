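"""Phasic/tonic EMG separation.

The tonic (gravity-compensating) component of a muscle's activity is estimated
as the average of the slow trials of a task, time-normalized to a common
length. Fast trials are ordered by movement mean velocity, averaged in
consecutive pairs, and the phasic component is obtained by subtracting the
tonic template from each averaged pair, finally normalized by the maximal EMG
value recorded in the task (phasic = (fast - tonic) / task_max).

Pre-processing chain (per raw trial): 30-300 Hz zero-phase band-pass,
rectification, 5 Hz zero-phase low-pass, then 100 ms sliding-window
trapezoidal integration. The band-pass is applied before rectification: the
rectified signal's envelope lives below 30 Hz, so rectifying first would hand
the envelope to the band-pass's high-pass edge and destroy it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_signals import EmgTrial, SampledSignal, sliding_window_integrate, zero_phase_filter
from .kinematics import MovementBounds

__all__ = [
    "CUT_MARGINS_S",
    "TonicTemplate",
    "PhasicTrace",
    "preprocess_emg",
    "cut_trial_window",
    "time_normalize",
    "build_tonic_template",
    "average_fast_pairs",
    "compute_phasic",
]

#: EMG cut margins around movement onset/offset, seconds (pre, post).
CUT_MARGINS_S = {"fast": (0.240, 0.090), "slow": (0.075, 0.075)}

#: Default normalized-time length.
DEFAULT_L = 1000


@dataclass(frozen=True)
class TonicTemplate:
    """Duration-normalized tonic EMG (mean of the slow trials of a task)."""

    muscle: str
    task: str
    values: np.ndarray
    source_count: int
    pre_margin_frac: float = 0.0  # fraction of the trace before movement onset
    post_margin_frac: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.source_count < 1:
            raise ValueError("tonic template needs at least one source trial")


@dataclass(frozen=True)
class PhasicTrace:
    """Unit-normalized phasic EMG of one averaged fast-trial pair.

    ``norm_constant * values + tonic`` reconstructs the averaged fast trace.
    ``duration_s`` is the mean movement duration of the averaged pair;
    ``window_s`` the full cut-window duration including margins.
    """

    muscle: str
    task: str
    direction: str
    values: np.ndarray
    duration_s: float
    window_s: float
    norm_constant: float
    tonic: np.ndarray
    pre_margin_frac: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "tonic", np.asarray(self.tonic, dtype=float))
        if self.norm_constant <= 0:
            raise ValueError("norm_constant must be > 0")
        if self.values.shape != self.tonic.shape:
            raise ValueError("phasic and tonic must have equal length")


def preprocess_emg(sig: SampledSignal, rectify_first: bool = False) -> SampledSignal:
    """Band-pass 30-300 Hz, rectify, low-pass 5 Hz, integrate (100 ms window).

    ``rectify_first=True`` applies rectification before the band-pass (the
    literal reading of the processing description); the default order is the
    one that preserves the rectified envelope.
    """
    if rectify_first:
        sig = sig.with_values(np.abs(sig.values))
        sig = zero_phase_filter(sig, "bandpass", (30.0, 300.0))
    else:
        sig = zero_phase_filter(sig, "bandpass", (30.0, 300.0))
        sig = sig.with_values(np.abs(sig.values))
    sig = zero_phase_filter(sig, "lowpass", 5.0)
    return sliding_window_integrate(sig, window_ms=100.0)


def cut_trial_window(trial_signal: SampledSignal, bounds: MovementBounds, speed: str) -> SampledSignal:
    """Cut a trial to its analysis window.

    Fast trials: 240 ms before onset to 90 ms after offset. Slow trials:
    75 ms margins on both sides.
    """
    if speed not in CUT_MARGINS_S:
        raise ValueError("speed must be 'slow' or 'fast'")
    pre, post = CUT_MARGINS_S[speed]
    rate = trial_signal.rate
    start = int(round((bounds.onset_s - trial_signal.t0 - pre) * rate))
    stop = int(round((bounds.offset_s - trial_signal.t0 + post) * rate))
    if start < 0:
        raise ValueError(
            f"insufficient pre-roll: window needs {pre*1000:.0f} ms before onset"
        )
    if stop >= len(trial_signal):
        raise ValueError(
            f"insufficient post-roll: window needs {post*1000:.0f} ms after offset"
        )
    vals = trial_signal.values[start : stop + 1]
    return SampledSignal(vals, rate=rate, t0=trial_signal.t0 + start / rate)


def time_normalize(values: np.ndarray, L: int = DEFAULT_L) -> np.ndarray:
    """Linear interpolation onto ``L`` evenly spaced points over the window."""
    if L < 2:
        raise ValueError("L must be >= 2")
    v = np.asarray(values, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    src = np.linspace(0.0, 1.0, v.shape[0])
    dst = np.linspace(0.0, 1.0, L)
    if v.ndim == 1:
        return np.interp(dst, src, v)
    return np.column_stack([np.interp(dst, src, v[:, j]) for j in range(v.shape[1])])


def build_tonic_template(
    slow_trials: Sequence[EmgTrial],
    bounds: Sequence[MovementBounds],
    L: int = DEFAULT_L,
    preprocessed: bool = False,
) -> TonicTemplate:
    """Average the (cut, integrated, time-normalized) slow trials of a task.

    Defective channels are excluded; at least one usable trial is required.
    ``preprocessed=True`` skips the raw-EMG filtering chain (for signals that
    are already integrated envelopes, e.g. the synthetic envelope mode).
    """
    usable = [(t, b) for t, b in zip(slow_trials, bounds) if t.usable]
    if not usable:
        raise ValueError("no usable slow trials to build a tonic template")
    traces = []
    margins = []
    for trial, b in usable:
        sig = trial.signal if preprocessed else preprocess_emg(trial.signal)
        cut = cut_trial_window(sig, b, "slow")
        traces.append(time_normalize(cut.values, L))
        pre, post = CUT_MARGINS_S["slow"]
        win = cut.duration
        margins.append((pre / win, post / win))
    pre_frac = float(np.mean([m[0] for m in margins]))
    post_frac = float(np.mean([m[1] for m in margins]))
    first = usable[0][0]
    return TonicTemplate(
        muscle=first.muscle,
        task=first.task,
        values=np.mean(traces, axis=0),
        source_count=len(usable),
        pre_margin_frac=pre_frac,
        post_margin_frac=post_frac,
    )


def average_fast_pairs(
    fast_trials: Sequence[EmgTrial],
    bounds: Sequence[MovementBounds],
    mean_velocities: Sequence[float],
    L: int = DEFAULT_L,
    preprocessed: bool = False,
) -> list[dict]:
    """Velocity-ordered pairwise averaging of fast trials.

    Usable trials are sorted ascending by movement mean velocity (stable sort,
    so velocity ties keep acquisition order), consecutive non-overlapping
    pairs are formed (an odd trailing trial - the fastest - is dropped), each
    pair is time-normalized and averaged. Returns one record per pair with the
    averaged trace, the pair mean movement duration and window duration.
    """
    items = [
        (t, b, v)
        for t, b, v in zip(fast_trials, bounds, mean_velocities)
        if t.usable
    ]
    if len(items) < 2:
        raise ValueError("need at least 2 usable fast trials to form a pair")
    order = np.argsort([v for _, _, v in items], kind="stable")
    items = [items[i] for i in order]
    if len(items) % 2:
        items = items[:-1]  # drop the single fastest trial

    pre, post = CUT_MARGINS_S["fast"]
    out = []
    for k in range(0, len(items), 2):
        pair = items[k : k + 2]
        traces, durs, wins = [], [], []
        for trial, b, _v in pair:
            sig = trial.signal if preprocessed else preprocess_emg(trial.signal)
            cut = cut_trial_window(sig, b, "fast")
            traces.append(time_normalize(cut.values, L))
            durs.append(b.duration_s)
            wins.append(cut.duration)
        dur = float(np.mean(durs))
        win = float(np.mean(wins))
        out.append(
            {
                "values": np.mean(traces, axis=0),
                "duration_s": dur,
                "window_s": win,
                "pre_margin_frac": pre / win,
                "pair_rank": k // 2,
                "direction": pair[0][0].direction,
                "muscle": pair[0][0].muscle,
                "task": pair[0][0].task,
            }
        )
    return out


def compute_phasic(fast_avg: dict, template: TonicTemplate, task_max: float) -> PhasicTrace:
    """Phasic = (fast - tonic) / task_max, in normalized time.

    ``task_max`` is the maximal integrated EMG recorded in the task for this
    participant and muscle; it puts all participants on a common scale.
    """
    if task_max <= 0:
        raise ValueError("task_max must be > 0")
    fast = np.asarray(fast_avg["values"], dtype=float)
    if fast.shape != template.values.shape:
        raise ValueError("fast trace and tonic template lengths differ")
    phasic = (fast - template.values) / task_max
    return PhasicTrace(
        muscle=fast_avg.get("muscle", template.muscle),
        task=fast_avg.get("task", template.task),
        direction=fast_avg.get("direction", "up"),
        values=phasic,
        duration_s=float(fast_avg["duration_s"]),
        window_s=float(fast_avg["window_s"]),
        norm_constant=float(task_max),
        tonic=template.values,
        pre_margin_frac=float(fast_avg.get("pre_margin_frac", 0.0)),
    )
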