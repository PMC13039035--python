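"""Indirect-calorimetry energetics for the treadmill experiment.

Metabolic power follows the Brockway linear combination
``P = 16.38 * VO2 + 4.64 * VCO2`` with the coefficients in J/mL, i.e. they
apply directly to gas-volume rates in mL/s. Breath files are ingested in
mL/min (the usual metabolic-cart export) and converted before the equation;
a config switch accepts L/min.

Per 3-minute walking block, the gross power is the time-weighted average of
per-breath power over the last minute of the block, the baseline is the
average over the window from 1 min to 30 s before block start (seated rest),
and the net metabolic power is (gross - baseline) / body mass in W/kg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_signals import BreathSeries

__all__ = [
    "C1_J_PER_ML",
    "C2_J_PER_ML",
    "BlockEnergetics",
    "metabolic_power",
    "breath_power",
    "net_steady_state_power",
]

C1_J_PER_ML = 16.38  # J per mL O2
C2_J_PER_ML = 4.64   # J per mL CO2

_UNIT_TO_ML_S = {"mL/s": 1.0, "mL/min": 1.0 / 60.0, "L/min": 1000.0 / 60.0}


@dataclass(frozen=True)
class BlockEnergetics:
    block: str
    condition: str
    gross_power_w: float
    baseline_power_w: float
    net_power_wkg: float
    mass: float


def metabolic_power(vo2, vco2, units: str = "mL/s"):
    """Brockway metabolic power in watts.

    ``vo2``/``vco2`` are gas-volume rates (scalar or array) in ``units``;
    with the default mL/s the empirical coefficients apply directly
    (16.38 and 4.64 J/mL).
    """
    if units not in _UNIT_TO_ML_S:
        raise ValueError(f"units must be one of {sorted(_UNIT_TO_ML_S)}")
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas-volume rates must be nonnegative")
    k = _UNIT_TO_ML_S[units]
    p = C1_J_PER_ML * vo2 * k + C2_J_PER_ML * vco2 * k
    return float(p) if p.ndim == 0 else p


def breath_power(series: BreathSeries, units: str = "mL/min") -> np.ndarray:
    """Per-breath metabolic power (W) of a breath series."""
    return metabolic_power(series.vo2, series.vco2, units=units)


def _time_weighted_mean(t: np.ndarray, p: np.ndarray, lo: float, hi: float, what: str) -> float:
    """Mean of per-breath power over [lo, hi], each breath weighted by the
    overlap of its inter-breath midpoint cell with the window."""
    inside = (t >= lo) & (t <= hi)
    if not inside.any():
        raise ValueError(f"empty {what} window [{lo:.1f}, {hi:.1f}] s")
    # Voronoi cell edges at inter-breath midpoints, clipped to the window
    edges = np.concatenate(([t[0]], (t[:-1] + t[1:]) / 2.0, [t[-1]]))
    left = np.clip(edges[:-1], lo, hi)
    right = np.clip(edges[1:], lo, hi)
    w = np.maximum(right - left, 0.0)
    if w.sum() <= 0:
        raise ValueError(f"empty {what} window [{lo:.1f}, {hi:.1f}] s")
    return float(np.sum(w * p) / w.sum())


def net_steady_state_power(
    series: BreathSeries,
    block_start: float,
    block_end: float,
    mass: float | None = None,
    block: str = "",
    condition: str = "",
    units: str = "mL/min",
) -> BlockEnergetics:
    """Net metabolic power of one walking block.

    gross = time-weighted mean power over the block's last minute
    ``[end - 60, end]``; baseline = the same over ``[start - 60, start - 30]``
    (seated rest); net = (gross - baseline) / mass in W/kg.
    """
    if mass is None:
        mass = series.mass
    if not mass > 0:
        raise ValueError("participant mass must be > 0")
    if block_end <= block_start:
        raise ValueError("block_end must exceed block_start")
    p = breath_power(series, units=units)
    gross = _time_weighted_mean(series.t, p, block_end - 60.0, block_end, "steady-state")
    base = _time_weighted_mean(series.t, p, block_start - 60.0, block_start - 30.0, "baseline")
    return BlockEnergetics(
        block=block,
        condition=condition,
        gross_power_w=gross,
        baseline_power_w=base,
        net_power_wkg=(gross - base) / mass,
        mass=float(mass),
    )
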