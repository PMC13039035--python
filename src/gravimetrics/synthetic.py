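"""Synthetic cohort generator.

Produces EMG, marker, breath and gait inputs with the statistical structure
the analysis pipeline assumes, so every stage can run and be validated
without the deposited recordings:

* per-trial EMG as a tonic (gravity-compensating, mildly posture-dependent)
  envelope plus, in fast trials, an agonist burst and an optional negative
  epoch of configured depth/duration placed in the gravity-assisted phase
  (deceleration of upward, acceleration of downward movements);
* slow/fast trial blocks for the four tasks with bell-shaped (minimum-jerk)
  kinematics and an age-group slowing of +3.5% on fast durations;
* a reduced negative-epoch depth for older adults in whole-body tasks only
  (the age x task-type interaction the statistics must detect);
* breath-by-breath gas exchange with a seated baseline, an exponential
  on-transient (tau = 30 s) and a steady plateau of configured net W/kg;
* periodic foot trajectories with configured step frequency/length and
  medio-lateral spacing (narrowed in the line-walking condition).

All generators are pure functions of (config, seed). Injected epochs have
raised-cosine shoulders (a square deactivation is non-physiological); their
ground-truth duration and amplitude are computed analytically from the pulse
shape at the -3*sigma detection level, independent of any pipeline code.

EMG can be emitted at two levels: ``"raw"`` (envelope times a broadband
carrier, to be passed through the full band-pass/rectify/low-pass/integrate
chain) or ``"envelope"`` (the integrated-EMG-scale envelope directly; the
level on which the noise model is specified).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_signals import BreathSeries, EmgTrial, MarkerTrajectory, SampledSignal, TASKS

__all__ = [
    "SynthConfig",
    "minimum_jerk",
    "synth_emg_trial",
    "synth_cohort",
    "synth_breath",
    "synth_gait",
    "injected_epoch_truth",
]

WB_TASKS = ("STS_BTS", "WBR_D1", "WBR_D2")

#: focal muscle synthesized per task (the antigravity muscles the analysis uses)
FOCAL_MUSCLE = {"ARM": "DA", "STS_BTS": "VL", "WBR_D1": "VL", "WBR_D2": "VL"}
SECONDARY_MUSCLE = {"STS_BTS": "ESL1", "WBR_D1": "ESL1", "WBR_D2": "ESL1"}


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the synthetic cohort.

    Group sizes, the +3.5% slowing of older adults and the whole-body-only
    depth reduction mirror the study design; amplitudes follow the printed
    task geometry (45 deg arm raise ~ 0.5 m hand excursion for an average
    arm; whole-body reaching to targets at 15%/30% of height). Noise defaults
    keep the -3*SD / 40 ms detector below a 5% false-positive rate on null
    trials.
    """

    n_young: int = 20
    n_older: int = 24
    older_slowdown: float = 0.035          # fractional fast-duration inflation

    # movement geometry/durations per task: (amplitude m, fast s, slow s)
    task_kinematics: dict = field(
        default_factory=lambda: {
            "ARM": (0.50, 0.45, 5.0),
            "STS_BTS": (0.35, 1.40, 5.0),
            "WBR_D1": (0.60, 1.20, 5.0),
            "WBR_D2": (0.75, 1.40, 5.0),
        }
    )
    # trials per direction: (n_slow, n_fast)
    trials_per_direction: dict = field(
        default_factory=lambda: {
            "ARM": (6, 12),
            "STS_BTS": (3, 6),
            "WBR_D1": (3, 6),
            "WBR_D2": (3, 6),
        }
    )

    # negative-epoch depth as a fraction of the tonic level
    depth_arm: float = 0.80                # both groups, arm task
    depth_wb_young: float = 0.90
    depth_wb_older: float = 0.56           # older adults exploit gravity less
    duration_frac: float = 0.20            # epoch flat core / movement duration
    shoulder_s: float = 0.15               # raised-cosine ramp time, s
    occurrence_p: float = 0.95             # probability a fast trial has an epoch

    tonic_base: float = 0.20               # mV, integrated-EMG scale
    tonic_phase_gain: float = 0.15         # posture dependence of the tonic
    burst_gain: float = 1.2                # agonist burst peak / tonic base
    emg_noise_sd: float = 0.05             # x tonic_base, integrated scale
    marker_noise_sd: float = 0.0005        # m
    emg_rate: float = 1000.0
    marker_rate: float = 200.0
    duration_jitter: float = 0.05          # lognormal sd of trial durations

    # experiment 2
    mass_kg: float = 70.0
    baseline_power_w: float = 80.0
    net_power_wkg: dict = field(
        default_factory=lambda: {"normal": 3.0, "line": 3.4}
    )
    rer: float = 0.85
    breath_interval_s: float = 3.0
    breath_noise: float = 0.03
    step_freq_hz: dict = field(default_factory=lambda: {"normal": 0.9, "line": 0.9})
    step_length_m: dict = field(default_factory=lambda: {"normal": 0.50, "line": 0.50})
    feet_spacing_m: dict = field(default_factory=lambda: {"normal": 0.18, "line": 0.06})

    def __post_init__(self):
        if self.n_young < 1 or self.n_older < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0.0 <= self.occurrence_p <= 1.0:
            raise ValueError("occurrence probability must lie in [0, 1]")
        for d in (self.depth_arm, self.depth_wb_young, self.depth_wb_older):
            if d < 0:
                raise ValueError("epoch depths must be >= 0")

    def depth(self, group: str, task: str) -> float:
        if task == "ARM":
            return self.depth_arm
        return self.depth_wb_young if group == "young" else self.depth_wb_older


def minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile 10u^3 - 15u^4 + 6u^5 on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _mj_crossing(level: float) -> float:
    """Phase u where the minimum-jerk profile reaches ``level``."""
    from scipy.optimize import brentq

    return float(brentq(lambda u: minimum_jerk(np.array([u]))[0] - level, 0.0, 1.0))


#: phase at which a minimum-jerk profile crosses 5% of its amplitude; the
#: operational (5%-95%) movement duration is (1 - 2 * U05) x true duration
U05 = _mj_crossing(0.05)
OPERATIONAL_FRACTION = 1.0 - 2.0 * U05


def _raised_cosine_window(t: np.ndarray, start: float, flat: float, ramp: float) -> np.ndarray:
    """0 -> 1 -> 0 window: cosine ramps of ``ramp`` s around a ``flat`` core."""
    w = np.zeros_like(t)
    up = (t >= start) & (t < start + ramp)
    w[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
    core = (t >= start + ramp) & (t <= start + ramp + flat)
    w[core] = 1.0
    dn = (t > start + ramp + flat) & (t <= start + 2 * ramp + flat)
    w[dn] = 0.5 * (1 + np.cos(np.pi * (t[dn] - start - ramp - flat) / ramp))
    return w


def injected_epoch_truth(
    depth: float,
    flat_s: float,
    ramp_s: float,
    movement_s: float,
    noise_sd_rel: float,
    sd_factor: float = 3.0,
) -> dict:
    """Analytic ground truth of an injected epoch at the detection level.

    The detector thresholds the phasic trace at ``-sd_factor * sigma``; with a
    pulse of depth ``depth`` (fraction of the local tonic) and noise of
    relative SD ``noise_sd_rel`` (fraction of the tonic), the threshold sits
    at relative level ``lam = sd_factor * noise_sd_rel / depth`` on the pulse.
    Returns the pulse width, duration fraction and mean amplitude over the
    supra-threshold interval, computed from the raised-cosine shape alone.
    """
    if depth <= 0:
        return {"duration_s": 0.0, "T": 0.0, "amplitude": np.nan, "detectable": False}
    lam = sd_factor * noise_sd_rel / depth
    if lam >= 1.0:
        return {"duration_s": 0.0, "T": 0.0, "amplitude": np.nan, "detectable": False}
    # cosine ramp w(tau) = (1 - cos(pi tau / R)) / 2 crosses lam at tau_lam
    tau_lam = ramp_s / math.pi * math.acos(1.0 - 2.0 * lam)
    width = flat_s + 2.0 * (ramp_s - tau_lam)
    # integral of w over the supra-threshold part of one ramp
    ramp_int = 0.5 * ((ramp_s - tau_lam) + ramp_s / math.pi * math.sin(math.pi * tau_lam / ramp_s))
    mean_w = (flat_s + 2.0 * ramp_int) / width
    return {
        "duration_s": width,
        "T": width / movement_s,
        "amplitude": -100.0 * depth * mean_w,
        "detectable": True,
    }


def _trial_timeline(duration_s: float, rate: float, pre_s: float = 0.9, post_s: float = 0.9):
    n = int(round((pre_s + duration_s + post_s) * rate)) + 1
    t = np.arange(n) / rate
    u = (t - pre_s) / duration_s  # movement phase, <0 before, >1 after
    return t, u


def synth_emg_trial(
    config: SynthConfig,
    group: str,
    task: str,
    speed: str,
    direction: str,
    trial_seed: int,
    signal_level: str = "raw",
    muscle: str | None = None,
    force_epoch: bool | None = None,
) -> dict:
    """One synthetic trial: EMG channel(s), a marker trajectory, ground truth.

    Returns a dict with keys ``emg`` (EmgTrial), ``marker``
    (MarkerTrajectory), ``duration_s``, ``mean_velocity`` and ``truth``.
    Same seed -> bitwise-identical output.
    """
    if group not in ("young", "older"):
        raise ValueError("group must be 'young' or 'older'")
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if signal_level not in ("raw", "envelope"):
        raise ValueError("signal_level must be 'raw' or 'envelope'")
    rng = np.random.default_rng(trial_seed)
    amp, fast_s, slow_s = config.task_kinematics[task]
    base_dur = fast_s if speed == "fast" else slow_s
    if speed == "fast" and group == "older":
        base_dur *= 1.0 + config.older_slowdown
    dur = float(base_dur * math.exp(rng.normal(0.0, config.duration_jitter)))

    t, u = _trial_timeline(dur, config.emg_rate)
    phase = np.clip(u, 0.0, 1.0)
    s = minimum_jerk(phase)

    tonic = config.tonic_base * (1.0 + config.tonic_phase_gain * s)
    env = tonic.copy()
    truth = {
        "group": group,
        "task": task,
        "speed": speed,
        "direction": direction,
        "duration_s": dur,
        "duration_op_s": dur * OPERATIONAL_FRACTION,  # 5%-95% bounds duration
        "has_epoch": False,
        "depth": 0.0,
        "epoch_duration_s": 0.0,
        "epoch_T": 0.0,
        "epoch_amplitude": np.nan,
        "clipped": False,
    }

    if speed == "fast":
        # agonist burst in the gravity-opposing phase, kept clear of the
        # pre-onset stable margin (which must contain noise only) and of the
        # injected epoch
        burst_center = 0.30 if direction == "up" else 0.70
        burst = (
            config.burst_gain
            * config.tonic_base
            * np.exp(-0.5 * ((u - burst_center) / 0.04) ** 2)
        )
        env = env + burst

        depth = config.depth(group, task)
        has_epoch = force_epoch if force_epoch is not None else bool(
            rng.random() < config.occurrence_p
        )
        if has_epoch and depth > 0:
            flat = config.duration_frac * dur
            ramp = min(config.shoulder_s, 0.1 * dur)
            # gravity-assisted phase: deceleration of upward, acceleration of
            # downward movements; kept inside the operational (5-95%) bounds
            # so the cut window does not truncate the epoch
            center = 0.62 if direction == "up" else 0.38
            # trial clock: movement begins at 0.9 s
            start = 0.9 + center * dur - (flat / 2.0 + ramp)
            w = _raised_cosine_window(t, start, flat, ramp)
            env = env - depth * tonic * w
            tonic_local = config.tonic_base * (
                1.0 + config.tonic_phase_gain * minimum_jerk(np.array([center]))[0]
            )
            tr = injected_epoch_truth(
                depth, flat, ramp, dur * OPERATIONAL_FRACTION,
                config.emg_noise_sd * config.tonic_base / tonic_local,
            )
            truth.update(
                has_epoch=True,
                depth=depth,
                epoch_duration_s=tr["duration_s"],
                epoch_T=tr["T"],
                epoch_amplitude=tr["amplitude"],
            )

    # noise on the integrated-EMG scale: white noise smoothed to ~5 Hz
    noise = rng.normal(0.0, 1.0, env.shape)
    kernel_n = max(3, int(round(0.05 * config.emg_rate)) | 1)
    kern = np.hanning(kernel_n)
    kern /= kern.sum()
    noise = np.convolve(noise, kern, mode="same")
    noise *= config.emg_noise_sd * config.tonic_base / max(noise.std(), 1e-12)
    env = env + noise
    if np.any(env < 0):
        truth["clipped"] = True
        env = np.maximum(env, 0.0)

    if signal_level == "raw":
        carrier = rng.normal(0.0, 1.0, env.shape)
        values = env * carrier
    else:
        values = env
    emg = EmgTrial(
        muscle=muscle or FOCAL_MUSCLE[task],
        side="right",
        task=task,
        speed=speed,
        direction=direction,
        signal=SampledSignal(values, rate=config.emg_rate),
    )

    # marker: minimum-jerk vertical displacement, sign per direction
    tm, um = _trial_timeline(dur, config.marker_rate)
    z = amp * minimum_jerk(np.clip(um, 0, 1)) * (1.0 if direction == "up" else -1.0)
    xyz = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    xyz = xyz + rng.normal(0.0, config.marker_noise_sd, xyz.shape)
    marker = MarkerTrajectory("endpoint", SampledSignal(xyz, rate=config.marker_rate))

    return {
        "emg": emg,
        "marker": marker,
        "duration_s": dur,
        "movement_onset_s": 0.9,
        "movement_offset_s": 0.9 + dur,
        "mean_velocity": amp / dur,
        "truth": truth,
    }


def synth_cohort(
    config: SynthConfig,
    seed: int,
    tasks: tuple[str, ...] = TASKS,
    signal_level: str = "envelope",
    muscles_per_task: dict | None = None,
) -> dict:
    """Full Experiment-1 dataset: per participant x task trial blocks + truth.

    Participants are ``Y01..`` (young) and ``O01..`` (older). The group
    contrast (reduced epoch depth) is injected only in whole-body tasks.
    Returns ``{"participants": {pid: {"group", "tasks": {task: {"muscle",
    "slow": [...], "fast": [...]}}}}, "truth": [...]}``.
    """
    if muscles_per_task is None:
        muscles_per_task = {t: [FOCAL_MUSCLE[t]] for t in tasks}
    root = np.random.default_rng(seed)
    participants = {}
    truth_rows = []
    pids = [("young", f"Y{i + 1:02d}") for i in range(config.n_young)] + [
        ("older", f"O{i + 1:02d}") for i in range(config.n_older)
    ]
    for group, pid in pids:
        ptasks = {}
        for task in tasks:
            n_slow, n_fast = config.trials_per_direction[task]
            per_muscle = {}
            for muscle in muscles_per_task[task]:
                slow, fast = [], []
                for direction in ("up", "down"):
                    for k in range(n_slow):
                        tseed = int(root.integers(0, 2**31 - 1))
                        slow.append(
                            synth_emg_trial(
                                config, group, task, "slow", direction, tseed,
                                signal_level=signal_level, muscle=muscle,
                            )
                        )
                    for k in range(n_fast):
                        tseed = int(root.integers(0, 2**31 - 1))
                        rec = synth_emg_trial(
                            config, group, task, "fast", direction, tseed,
                            signal_level=signal_level, muscle=muscle,
                        )
                        fast.append(rec)
                        row = dict(rec["truth"])
                        row.update(participant=pid, muscle=muscle)
                        truth_rows.append(row)
                per_muscle[muscle] = {"slow": slow, "fast": fast}
            ptasks[task] = per_muscle
        participants[pid] = {"group": group, "tasks": ptasks}
    return {"participants": participants, "truth": truth_rows}


def synth_breath(
    config: SynthConfig,
    condition: str,
    seed: int,
    block_start: float = 120.0,
    block_len: float = 180.0,
    tau_s: float = 30.0,
) -> dict:
    """Breath series for one walking block with known net power.

    Seated baseline before ``block_start``, exponential on-transient of time
    constant ``tau_s`` toward baseline + net * mass during the block,
    exponential recovery after. Returns the series, block timing and truth.
    """
    if condition not in config.net_power_wkg:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    net_w = config.net_power_wkg[condition] * config.mass_kg
    total = block_start + block_len + 60.0
    times = []
    tcur = 0.0
    while tcur < total:
        tcur += config.breath_interval_s * math.exp(rng.normal(0.0, 0.15))
        times.append(tcur)
    t = np.array(times)
    p = np.full_like(t, config.baseline_power_w)
    in_block = (t >= block_start) & (t <= block_start + block_len)
    p[in_block] += net_w * (1.0 - np.exp(-(t[in_block] - block_start) / tau_s))
    after = t > block_start + block_len
    p_end = net_w * (1.0 - math.exp(-block_len / tau_s))
    p[after] += p_end * np.exp(-(t[after] - block_start - block_len) / tau_s)

    # invert Brockway at fixed RER: P[W] = (16.38 + 4.64 * rer) * vo2[mL/s]
    vo2_ml_s = p / (16.38 + 4.64 * config.rer)
    vo2 = vo2_ml_s * 60.0 * np.exp(rng.normal(0.0, config.breath_noise, t.shape))
    vco2 = vo2_ml_s * config.rer * 60.0 * np.exp(rng.normal(0.0, config.breath_noise, t.shape))
    series = BreathSeries(t=t, vo2=vo2, vco2=vco2, mass=config.mass_kg)
    return {
        "series": series,
        "block_start": block_start,
        "block_end": block_start + block_len,
        "truth_net_wkg": config.net_power_wkg[condition],
    }


def synth_gait(
    config: SynthConfig,
    condition: str,
    seed: int,
    duration_s: float = 60.0,
) -> dict:
    """Periodic foot marker trajectories with known gait parameters."""
    if condition not in config.feet_spacing_m:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    rate = config.marker_rate
    n = int(round(duration_s * rate)) + 1
    t = np.arange(n) / rate
    f = config.step_freq_hz[condition]
    half_len = config.step_length_m[condition] / 2.0
    spacing = config.feet_spacing_m[condition]
    noise = lambda: rng.normal(0.0, config.marker_noise_sd, n)

    rx = half_len * np.sin(2 * np.pi * f * t) + noise()
    lx = half_len * np.sin(2 * np.pi * f * t + np.pi) + noise()
    ry = -spacing / 2.0 + noise()
    ly = spacing / 2.0 + noise()
    z = np.zeros(n)
    right = MarkerTrajectory("right_foot", SampledSignal(np.column_stack([rx, ry, z]), rate=rate))
    left = MarkerTrajectory("left_foot", SampledSignal(np.column_stack([lx, ly, z]), rate=rate))
    return {
        "left": left,
        "right": right,
        "truth": {
            "step_rate": f,
            "step_length": 2 * half_len,
            "feet_spacing": spacing,
        },
    }
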