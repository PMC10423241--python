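"""Preprocessing formulas that turn raw measurements into analysis features.

These are the standard derivations for this kind of multimodal spine
dataset: mono-exponential T2 from a multi-echo MRI decay curve, Dixon fat
fraction, pre/post change scores (temporal summation, exercise-induced
hypoalgesia), slice-area-to-volume scaling, and left/right or trial
pooling.  The clustering pipeline consumes already-derived feature tables;
this module is the toolkit that produces them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import DomainError, FitFailureError

#: Echo times (ms) of the sagittal spin-echo multi-echo protocol.
DEFAULT_ECHO_TIMES_MS = (15.75, 36.75, 57.75, 78.75, 99.75, 120.75, 141.75, 162.75)

#: Slice pitch (mm) for disc volumes: 3.5 mm thickness + 1.0 mm gap.
DISC_SLICE_PITCH_MM = 4.5
#: Slice pitch (mm) for paraspinal muscle volumes (contiguous 3.5 mm slices).
MUSCLE_SLICE_PITCH_MM = 3.5


@dataclass(frozen=True)
class EchoSeries:
    """A T2 decay curve: echo times (ms) and signal intensities, aligned."""

    echo_times: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self):
        te = np.asarray(self.echo_times, dtype=float)
        s = np.asarray(self.intensities, dtype=float)
        if te.size != s.size:
            raise DomainError("echo_times and intensities must be aligned")
        if te.size < 3:
            raise DomainError("need at least 3 echoes for a T2 fit")
        if not np.all(np.diff(te) > 0):
            raise DomainError("echo_times must be strictly increasing")
        if np.any(s <= 0):
            raise DomainError("intensities must be positive for a log-linear fit")


def t2_from_echoes(series: EchoSeries) -> float:
    """T2 (ms) from an ordinary least-squares fit of ln(intensity) on TE.

    The mono-exponential model S(TE) = S0 * exp(-TE/T2) is linear in log
    space with slope -1/T2; a non-negative slope means the signal does not
    decay and the fit is rejected.
    """
    te = np.asarray(series.echo_times, dtype=float)
    log_s = np.log(np.asarray(series.intensities, dtype=float))
    slope, _intercept = np.polyfit(te, log_s, 1)
    if slope >= 0:
        raise FitFailureError(f"non-decaying signal (slope {slope:.4g} >= 0)")
    return -1.0 / slope


def fat_fraction(signal_fat: float, signal_water: float) -> float:
    """Dixon fat fraction in percent: 100 * fat / (fat + water)."""
    if signal_fat < 0 or signal_water < 0:
        raise DomainError("signal intensities must be non-negative")
    total = signal_fat + signal_water
    if total == 0:
        raise DomainError("fat and water signals are both zero")
    return 100.0 * signal_fat / total


def change_score(later: float, earlier: float) -> float:
    """later - earlier.

    Temporal summation: 10th minus 1st pulse rating.  Exercise-induced
    hypoalgesia: post- minus pre-exercise PPT, so positive values mean
    thresholds increased.
    """
    return later - earlier


def slice_volume(areas_mm2: Sequence[float], slice_pitch_mm: float) -> float:
    """Volume in cm^3 from per-slice areas (mm^2) scaled by the slice pitch."""
    areas = np.asarray(list(areas_mm2), dtype=float)
    if areas.size == 0:
        raise DomainError("areas must be non-empty")
    if np.any(areas < 0):
        raise DomainError("areas must be non-negative")
    if slice_pitch_mm <= 0:
        raise DomainError("slice pitch must be positive")
    return float(areas.sum() * slice_pitch_mm / 1000.0)  # mm^3 -> cm^3


class PoolRule(str, Enum):
    MEAN = "mean"
    MAX = "max"


def pool_measurements(values: Sequence[float], rule: PoolRule | str = PoolRule.MEAN) -> float:
    """Pool repeated trials or left/right sides: arithmetic mean or maximum."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise DomainError("values must be non-empty")
    rule = PoolRule(rule)
    return float(vals.mean() if rule is PoolRule.MEAN else vals.max())
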