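"""File ingestion and shared signal primitives.

Every downstream stage (EMG processing, kinematics, energetics) consumes the
containers and filters defined here: uniformly sampled time series, zero-phase
Butterworth filtering, and 100 ms sliding-window trapezoidal integration.

Motion files are accepted either as C3D (requires the optional ``ezc3d``
package) or as a plain CSV dialect with a header row
``time,<label>_x,<label>_y,<label>_z,...`` in meters/seconds. Breath-by-breath
gas exchange is a CSV with columns ``time_s,vo2,vco2``; breath timestamps are
irregular by nature and are preserved as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "SampledSignal",
    "EmgTrial",
    "MarkerTrajectory",
    "BreathSeries",
    "MUSCLES",
    "TASKS",
    "read_motion_file",
    "write_motion_file",
    "read_breath_file",
    "write_breath_file",
    "zero_phase_filter",
    "sliding_window_integrate",
]

#: Recognized surface-EMG muscle labels (bilateral electrodes share the label).
MUSCLES = ("DA", "DP", "VL", "BF", "ESL1", "EST7", "TA", "SOL")

#: Task identifiers: focal arm raising, sit-to-stand/back-to-sit, and
#: whole-body reaching to targets at 15% (D1) / 30% (D2) of body height.
TASKS = ("ARM", "STS_BTS", "WBR_D1", "WBR_D2")

_MAX_NAN_RUN = 10  # samples; longer dropout gaps are considered unrecoverable


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled scalar or multi-column time series.

    Parameters
    ----------
    values : ndarray, shape (n,) or (n, k)
        Sample values; must be finite.
    rate : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not self.rate > 0:
            raise ValueError("sampling rate must be > 0")
        if not np.all(np.isfinite(v)):
            raise ValueError("signal values must be finite")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.rate

    def with_values(self, values: np.ndarray) -> "SampledSignal":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class EmgTrial:
    """One EMG channel recording of one movement trial."""

    muscle: str
    side: str  # "left" | "right"
    task: str
    speed: str  # "slow" | "fast"
    direction: str  # "up" | "down"
    signal: SampledSignal
    quality_flag: str = "ok"  # "ok" | "defective"

    def __post_init__(self):
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle label {self.muscle!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.speed not in ("slow", "fast"):
            raise ValueError(f"speed must be slow|fast, got {self.speed!r}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up|down, got {self.direction!r}")
        if self.quality_flag not in ("ok", "defective"):
            raise ValueError("quality_flag must be ok|defective")

    @property
    def usable(self) -> bool:
        return self.quality_flag == "ok"


@dataclass(frozen=True)
class MarkerTrajectory:
    """A labelled 3-D marker path.

    Coordinate convention: X antero-posterior (forward +), Y medio-lateral,
    Z vertical (up +).
    """

    label: str
    xyz: SampledSignal

    def __post_init__(self):
        if self.xyz.values.ndim != 2 or self.xyz.values.shape[1] != 3:
            raise ValueError("marker trajectory must have 3 columns (x, y, z)")


@dataclass(frozen=True)
class BreathSeries:
    """Breath-by-breath gas exchange (irregular timestamps).

    VO2/VCO2 are gas-volume rates; the package convention is mL/min on disk
    (the usual metabolic-cart export), converted where needed by the
    energetics module.
    """

    t: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    mass: float = float("nan")

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        vo2 = np.asarray(self.vo2, dtype=float)
        vco2 = np.asarray(self.vco2, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "vo2", vo2)
        object.__setattr__(self, "vco2", vco2)
        if not (len(t) == len(vo2) == len(vco2)):
            raise ValueError("t, vo2, vco2 must have equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("breath timestamps must be strictly increasing")
        if np.any(vo2 < 0) or np.any(vco2 < 0):
            raise ValueError("gas volumes must be nonnegative")


# ---------------------------------------------------------------------------
# filtering / integration primitives
# ---------------------------------------------------------------------------

def zero_phase_filter(
    sig: SampledSignal,
    kind: str,
    cutoff_hz,
    order: int = 3,
) -> SampledSignal:
    """Forward-backward Butterworth filter (zero net phase shift).

    ``kind`` is ``"lowpass"`` or ``"bandpass"``; ``cutoff_hz`` is a scalar or
    a (low, high) pair strictly inside (0, rate/2). Edges are handled by
    reflect padding over 3x the filter order, which keeps a constant signal
    exactly constant and preserves linearity.
    """
    nyq = sig.rate / 2.0
    cut = np.atleast_1d(np.asarray(cutoff_hz, dtype=float))
    if kind == "lowpass":
        if cut.size != 1:
            raise ValueError("lowpass expects a single cutoff")
    elif kind == "bandpass":
        if cut.size != 2 or cut[0] >= cut[1]:
            raise ValueError("bandpass expects an increasing (low, high) pair")
    else:
        raise ValueError("kind must be 'lowpass' or 'bandpass'")
    if np.any(cut <= 0) or np.any(cut >= nyq):
        raise ValueError(f"cutoff(s) {cut} must lie strictly inside (0, {nyq}) Hz")
    wn = float(cut[0] / nyq) if kind == "lowpass" else cut / nyq
    sos = sps.butter(order, wn, btype=kind, output="sos")
    padlen = 3 * order * 2  # per-section warm-up; generous, still small
    if len(sig) <= padlen:
        raise ValueError(
            f"signal of {len(sig)} samples too short for order-{order} "
            f"zero-phase filtering (needs > {padlen})"
        )
    out = sps.sosfiltfilt(sos, sig.values, axis=0, padtype="even", padlen=padlen)
    return sig.with_values(out)


def sliding_window_integrate(sig: SampledSignal, window_ms: float = 100.0) -> SampledSignal:
    """Centered sliding-window trapezoidal integration.

    Each output sample is the trapezoidal integral of the input over a window
    of ``window_ms`` centered on that sample; windows overhanging the edges
    are truncated. Units are input units x seconds.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be > 0")
    half = int(round(window_ms * sig.rate / 1000.0 / 2.0))
    if half < 1:
        raise ValueError("window must span at least 2 samples")
    n = len(sig)
    ct = cumulative_trapezoid(sig.values, dx=1.0 / sig.rate, initial=0.0, axis=0)
    lo = np.clip(np.arange(n) - half, 0, n - 1)
    hi = np.clip(np.arange(n) + half, 0, n - 1)
    out = ct[hi] - ct[lo]
    return sig.with_values(out)


# ---------------------------------------------------------------------------
# motion files
# ---------------------------------------------------------------------------

def _interpolate_short_gaps(arr: np.ndarray, label: str) -> np.ndarray:
    """Linearly fill NaN runs of <= _MAX_NAN_RUN samples; longer runs are fatal."""
    arr = arr.copy()
    for col in range(arr.shape[1]):
        x = arr[:, col]
        isnan = np.isnan(x)
        if not isnan.any():
            continue
        # locate runs
        idx = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
        starts, ends = idx[0::2], idx[1::2]
        if np.any(ends - starts > _MAX_NAN_RUN) or isnan[0] or isnan[-1]:
            raise ValueError(
                f"marker {label!r}: NaN gap longer than {_MAX_NAN_RUN} samples "
                "(or at the record edge)"
            )
        good = ~isnan
        x[isnan] = np.interp(np.flatnonzero(isnan), np.flatnonzero(good), x[good])
        arr[:, col] = x
    return arr


def read_motion_file(path, dialect: str = "csv") -> list[MarkerTrajectory]:
    """Read marker trajectories from a C3D or CSV motion file.

    The CSV dialect has a ``time`` column plus ``<label>_x/_y/_z`` triplets,
    units meters and seconds. Sampling must be uniform within 1e-6 relative
    tolerance; NaN gaps of at most 10 samples are linearly interpolated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "c3d":
        return _read_c3d(path)
    if dialect != "csv":
        raise ValueError("dialect must be 'c3d' or 'csv'")

    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("motion CSV must have a 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("motion file must contain at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * abs(np.median(dt)):
        raise ValueError("non-uniform sampling in motion CSV")
    rate = 1.0 / float(np.median(dt))

    labels: list[str] = []
    for c in df.columns:
        if c.endswith("_x"):
            labels.append(c[:-2])
    out = []
    for lab in labels:
        cols = [f"{lab}_x", f"{lab}_y", f"{lab}_z"]
        if not all(c in df.columns for c in cols):
            raise ValueError(f"marker {lab!r}: incomplete x/y/z triplet")
        arr = df[cols].to_numpy(dtype=float)
        arr = _interpolate_short_gaps(arr, lab)
        out.append(MarkerTrajectory(lab, SampledSignal(arr, rate=rate, t0=float(t[0]))))
    if not out:
        raise ValueError("no marker columns found")
    return out


def _read_c3d(path: Path) -> list[MarkerTrajectory]:
    try:
        import ezc3d  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D files requires the optional 'ezc3d' package; "
            "install it or convert the file to the CSV motion dialect"
        ) from exc
    c3d = ezc3d.c3d(str(path))
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    labels = [str(s).strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    pts = np.asarray(c3d["data"]["points"])  # (4, n_markers, n_frames)
    out = []
    for i, lab in enumerate(labels):
        arr = pts[:3, i, :].T / 1000.0  # C3D stores mm
        arr = _interpolate_short_gaps(arr, lab)
        out.append(MarkerTrajectory(lab, SampledSignal(arr, rate=rate)))
    return out


def write_motion_file(path, markers: Sequence[MarkerTrajectory]) -> None:
    """Write markers to the CSV motion dialect (UTF-8, LF)."""
    if not markers:
        raise ValueError("nothing to write")
    rate = markers[0].xyz.rate
    n = len(markers[0].xyz)
    data = {"time": markers[0].xyz.times}
    for m in markers:
        if len(m.xyz) != n or m.xyz.rate != rate:
            raise ValueError("all markers must share length and rate")
        for j, ax in enumerate("xyz"):
            data[f"{m.label}_{ax}"] = m.xyz.values[:, j]
    pd.DataFrame(data).to_csv(path, index=False, lineterminator="\n", float_format="%.9g")


# ---------------------------------------------------------------------------
# breath files
# ---------------------------------------------------------------------------

def read_breath_file(path, mass: float = float("nan")) -> BreathSeries:
    """Read a breath-by-breath CSV with columns ``time_s,vo2,vco2``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in ("time_s", "vo2", "vco2"):
        if col not in df.columns:
            raise ValueError(f"breath CSV missing column {col!r}")
    return BreathSeries(
        t=df["time_s"].to_numpy(dtype=float),
        vo2=df["vo2"].to_numpy(dtype=float),
        vco2=df["vco2"].to_numpy(dtype=float),
        mass=mass,
    )


def write_breath_file(path, series: BreathSeries) -> None:
    pd.DataFrame({"time_s": series.t, "vo2": series.vo2, "vco2": series.vco2}).to_csv(
        path, index=False, lineterminator="\n", float_format="%.9g"
    )
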