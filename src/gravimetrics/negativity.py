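"""Negative-epoch detection and negativity metrics on phasic EMG.

A negative epoch is a maximal interval where the phasic signal stays below
minus three times the standard deviation of the stable phase preceding the
movement, for at least 40 ms of real time. Per epoch:

* ``NA`` - negative area, trapezoidal integral of the phasic signal over the
  epoch in normalized time (always <= 0);
* ``TA`` - tonic area, same integral of the tonic signal (> 0);
* ``T``  - epoch duration divided by movement duration;
* ``index`` = T * NA / TA (<= 0; lower = the muscle exploits gravity more);
* ``amplitude`` = 100 * mean(phasic) / mean(tonic) over the epoch
  (-100: muscle fully silent; 0: exact gravity compensation).

Both phasic and tonic enter these ratios in the same (task-max-normalized)
units, so every metric is invariant to the normalization constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .phasic_tonic import PhasicTrace

__all__ = [
    "MIN_EPOCH_S",
    "SD_FACTOR",
    "NegativityEpoch",
    "pre_movement_sd",
    "detect_negative_epochs",
    "epoch_metrics",
    "trial_negativity",
    "aggregate_negativity",
    "ANTIGRAVITY_FOCUS",
]

MIN_EPOCH_S = 0.040   # minimum real-time epoch duration
SD_FACTOR = 3.0       # detection threshold = -SD_FACTOR * pre-movement SD

#: Focal antigravity muscles entering the aggregates: the anterior deltoid for
#: arm movements, vastus lateralis + erector spinae L1 for whole-body tasks.
ANTIGRAVITY_FOCUS = {
    "ARM": ("DA",),
    "STS_BTS": ("VL", "ESL1"),
    "WBR_D1": ("VL", "ESL1"),
    "WBR_D2": ("VL", "ESL1"),
}


@dataclass(frozen=True)
class NegativityEpoch:
    onset_n: float   # normalized time in [0, 1]
    offset_n: float
    NA: float
    TA: float
    T: float
    index: float
    amplitude: float

    def __post_init__(self):
        if not 0.0 <= self.onset_n <= self.offset_n <= 1.0:
            raise ValueError("epoch bounds must satisfy 0 <= onset <= offset <= 1")
        if self.NA > 0:
            raise ValueError("NA must be <= 0")
        if self.TA <= 0:
            raise ValueError("TA must be > 0")
        if not 0.0 < self.T <= 1.0 + 1e-12:
            raise ValueError("T must lie in (0, 1]")


def pre_movement_sd(phasic: PhasicTrace) -> float:
    """SD of the stable pre-onset margin of the (normalized) phasic trace."""
    L = phasic.values.shape[0]
    k = int(round(phasic.pre_margin_frac * L))
    if k < 2:
        return 0.0
    return float(np.std(phasic.values[:k], ddof=1))


def detect_negative_epochs(
    phasic: PhasicTrace,
    pre_sd: float | None = None,
    min_epoch_s: float = MIN_EPOCH_S,
) -> list[tuple[int, int]]:
    """Maximal sample runs with phasic < -3*SD lasting >= 40 ms.

    Returns ``(first, last)`` inclusive sample-index pairs; an empty list is a
    valid result. Real-time epoch length is the normalized run length times
    the cut-window duration.
    """
    if pre_sd is None:
        pre_sd = pre_movement_sd(phasic)
    if pre_sd < 0:
        raise ValueError("pre-movement SD must be >= 0")
    v = phasic.values
    L = v.shape[0]
    below = v < -SD_FACTOR * pre_sd
    if not below.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    runs = list(zip(edges[0::2], edges[1::2] - 1))
    out = []
    for first, last in runs:
        dur = (last - first) / (L - 1) * phasic.window_s
        if dur >= min_epoch_s - 1e-12:
            out.append((int(first), int(last)))
    return out


def epoch_metrics(
    interval: tuple[int, int],
    phasic: PhasicTrace,
) -> NegativityEpoch | None:
    """Eq.-style metrics of one detected epoch; ``None`` if the tonic is silent.

    Areas use trapezoidal quadrature on the normalized-time grid; the tonic is
    brought to the same normalized units as the phasic before integrating, so
    index and amplitude do not depend on the task-max constant.
    """
    first, last = interval
    L = phasic.values.shape[0]
    du = 1.0 / (L - 1)
    p = phasic.values[first : last + 1]
    tonic_norm = phasic.tonic / phasic.norm_constant
    s = tonic_norm[first : last + 1]
    NA = float(np.trapezoid(np.minimum(p, 0.0), dx=du))
    TA = float(np.trapezoid(s, dx=du))
    if TA <= 0:
        warnings.warn("epoch discarded: tonic area is zero over the epoch")
        return None
    epoch_s = (last - first) * du * phasic.window_s
    T = epoch_s / phasic.duration_s
    T = min(T, 1.0)
    mean_p = float(p.mean())
    mean_t = float(s.mean())
    return NegativityEpoch(
        onset_n=first * du,
        offset_n=last * du,
        NA=NA,
        TA=TA,
        T=T,
        index=T * NA / TA,
        amplitude=100.0 * mean_p / mean_t,
    )


def trial_negativity(phasic: PhasicTrace, pre_sd: float | None = None) -> dict:
    """Per-trial (per averaged pair) negativity summary.

    Multiple epochs combine additively: indices and durations sum (areas are
    additive), the amplitude is the epoch-duration-weighted mean. A trial with
    no epoch contributes index 0, occurrence 0, duration 0 and a missing
    amplitude.
    """
    intervals = detect_negative_epochs(phasic, pre_sd)
    epochs = [e for e in (epoch_metrics(iv, phasic) for iv in intervals) if e is not None]
    if not epochs:
        return {
            "n_epochs": 0,
            "index": 0.0,
            "occurrence": 0,
            "duration": 0.0,
            "amplitude": np.nan,
        }
    T_sum = sum(e.T for e in epochs)
    amp = sum(e.amplitude * e.T for e in epochs) / T_sum
    return {
        "n_epochs": len(epochs),
        "index": sum(e.index for e in epochs),
        "occurrence": 1,
        "duration": T_sum,
        "amplitude": amp,
    }


def aggregate_negativity(
    trials: pd.DataFrame,
    task_groups: dict[str, Sequence[str]] | None = None,
    muscle_focus: dict[str, Sequence[str]] = ANTIGRAVITY_FOCUS,
) -> pd.DataFrame:
    """Participant-level aggregation of per-trial negativity metrics.

    ``trials`` is the tidy per-trial table (columns: participant, group, task,
    muscle, trial, index, occurrence, duration, amplitude). Averaging order:
    over trials within participant x task x muscle, then over the configured
    focal muscles of the task, then over the tasks of each requested grouping
    (default: ARM alone and WB = mean of the three whole-body tasks). Empty
    cells stay missing, never zero-filled.
    """
    if task_groups is None:
        task_groups = {"ARM": ["ARM"], "WB": ["STS_BTS", "WBR_D1", "WBR_D2"]}
    metrics = ["index", "occurrence", "duration", "amplitude"]

    keep = []
    for task, muscles in muscle_focus.items():
        sub = trials[(trials["task"] == task) & (trials["muscle"].isin(muscles))]
        keep.append(sub)
    focus = pd.concat(keep, ignore_index=True) if keep else trials.iloc[0:0]

    per_muscle = (
        focus.groupby(["participant", "group", "task", "muscle"])[metrics]
        .mean()
        .reset_index()
    )
    per_task = (
        per_muscle.groupby(["participant", "group", "task"])[metrics].mean().reset_index()
    )

    rows = []
    for label, tasks in task_groups.items():
        sub = per_task[per_task["task"].isin(list(tasks))]
        agg = sub.groupby(["participant", "group"])[metrics].mean().reset_index()
        agg.insert(2, "task_group", label)
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)
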