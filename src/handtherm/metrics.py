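"""Dynamic thermal metrics extracted from finger ROIs.

Per finger (and as an unweighted five-finger hand mean) the pipeline reports

====  ======================================================================
T_init  mean ROI temperature of the last static frame (°C)
T_C     mean ROI temperature at cooling removal, i.e. the first rewarming
        frame (°C)
T_R     mean ROI temperature at the end of the 180 s rewarming window (°C)
ΔT_C    total change due to cold provocation, T_init − T_C (°C)
ΔT_R    total change due to rewarming, T_R − T_C (°C)
S_C     area under the cooling curve, ∫ (T_init − T(t)) dt over the cooling
        window — the cooling deficit, positive (°C·s)
S_R     area under the heating curve, ∫ (T(t) − T_C) dt over the rewarming
        window (°C·s)
contrast  S_R − S_C (°C·s)
====  ======================================================================

Areas use the trapezoidal rule on the per-frame curve samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import colormaps

from handtherm.segmentation import FingerROI
from handtherm.synthetic import FINGER_LABELS, ThermalSequence, Thermogram

__all__ = [
    "ThermalCurve",
    "Keyframes",
    "DynamicMetrics",
    "roi_mean_temperature",
    "build_curves",
    "area_under_curve",
    "compute_metrics",
    "intensity_map",
    "METRIC_FIELDS",
]

METRIC_FIELDS = ("t_init", "t_c", "t_r", "dt_c", "dt_r", "s_c", "s_r", "contrast")


@dataclass(frozen=True)
class ThermalCurve:
    """Mean ROI temperature versus time within one phase for one finger."""

    finger: str
    times: np.ndarray  # s from phase start, strictly increasing
    values: np.ndarray  # °C
    phase: str  # "cooling" | "rewarming"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class Keyframes:
    """Per-finger keyframe temperatures (°C), thumb→little."""

    t_init: np.ndarray
    t_c: np.ndarray
    t_r: np.ndarray


@dataclass(frozen=True)
class DynamicMetrics:
    """Per-finger metric table plus hand means (unweighted over five fingers)."""

    per_finger: pd.DataFrame  # index = finger labels, columns = METRIC_FIELDS
    conventions: dict

    @property
    def hand_mean(self) -> pd.Series:
        return self.per_finger.mean(axis=0)

    def to_frame(self, subject_id: str = "", group: str = "") -> pd.DataFrame:
        rows = self.per_finger.copy()
        rows.insert(0, "finger", rows.index)
        hand = self.hand_mean.to_frame().T
        hand.insert(0, "finger", "hand_mean")
        out = pd.concat([rows, hand], ignore_index=True)
        out.insert(0, "group", group)
        out.insert(0, "subject_id", subject_id)
        return out


def roi_mean_temperature(frame: Thermogram, roi: FingerROI) -> float:
    """Arithmetic mean temperature over the ROI's pixel path."""
    if roi.length == 0:
        raise ValueError("empty ROI")
    temp = frame.temperature
    rows, cols = roi.rows_cols()
    if (rows.min() < 0 or cols.min() < 0 or rows.max() >= temp.shape[0]
            or cols.max() >= temp.shape[1]):
        raise ValueError("ROI extends outside the frame")
    return float(temp[rows, cols].mean(dtype=np.float64))


def build_curves(sequence: ThermalSequence, rois: list[FingerROI]
                 ) -> tuple[list[ThermalCurve], Keyframes]:
    """Sample every cooling and rewarming frame through the five ROIs.

    Keyframes: T_init from the last static frame, T_C from the first
    rewarming frame (cooling removal), T_R from the last rewarming frame.
    The static-frame ROI is reused for all frames (the scene does not move).
    """
    for phase in ("static", "cooling", "rewarming"):
        if not sequence.phase_frames(phase):
            raise ValueError(f"sequence is missing the {phase!r} phase")
    curves: list[ThermalCurve] = []
    for phase in ("cooling", "rewarming"):
        frames = sequence.phase_frames(phase)
        times = np.array([f.time_s for f in frames])
        for roi in rois:
            vals = np.array([roi_mean_temperature(f, roi) for f in frames])
            curves.append(ThermalCurve(finger=roi.label, times=times,
                                       values=vals, phase=phase))
    static = sequence.phase_frames("static")[-1]
    warm = sequence.phase_frames("rewarming")
    kf = Keyframes(
        t_init=np.array([roi_mean_temperature(static, r) for r in rois]),
        t_c=np.array([roi_mean_temperature(warm[0], r) for r in rois]),
        t_r=np.array([roi_mean_temperature(warm[-1], r) for r in rois]),
    )
    return curves, kf


def area_under_curve(curve: ThermalCurve, baseline: float) -> float:
    """Signed trapezoidal integral of (value − baseline) over the curve."""
    if len(curve.times) < 2:
        raise ValueError("need at least 2 samples to integrate")
    return float(np.trapezoid(curve.values - baseline, curve.times))


def compute_metrics(curves: list[ThermalCurve], keyframes: Keyframes
                    ) -> DynamicMetrics:
    """Assemble the per-finger and hand-mean dynamic metric table."""
    by_finger = {(c.finger, c.phase): c for c in curves}
    rows = {}
    for i, label in enumerate(FINGER_LABELS):
        if (label, "rewarming") not in by_finger:
            raise ValueError(f"missing rewarming curve for {label}")
        t_init = float(keyframes.t_init[i])
        t_c = float(keyframes.t_c[i])
        t_r = float(keyframes.t_r[i])
        cool = by_finger.get((label, "cooling"))
        # cooling deficit relative to baseline, positive when fingers cooled
        s_c = -area_under_curve(cool, t_init) if cool is not None else np.nan
        s_r = area_under_curve(by_finger[label, "rewarming"], t_c)
        rows[label] = dict(t_init=t_init, t_c=t_c, t_r=t_r,
                           dt_c=t_init - t_c, dt_r=t_r - t_c,
                           s_c=s_c, s_r=s_r, contrast=s_r - s_c)
    table = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_FIELDS)]
    return DynamicMetrics(
        per_finger=table,
        conventions={
            "s_c": "integral of (T_init - T(t)) over the cooling window",
            "s_r": "integral of (T(t) - T_C) over the rewarming window",
            "t_c": "first rewarming frame (cooling removal)",
            "t_r": "last rewarming frame",
            "quadrature": "trapezoid",
            "hand_mean": "unweighted mean over five fingers",
        },
    )


def intensity_map(frame: Thermogram, t_range: tuple[float, float],
                  cmap: str = "inferno") -> np.ndarray:
    """Deterministic temperature→colour rendering (RGB float array).

    Pure visualization; normalization matches the greyscale conversion so a
    grey level g corresponds to the colour at g/255 on the same window.
    """
    t_min, t_max = t_range
    if t_min >= t_max:
        raise ValueError("invalid temperature range")
    norm = (np.clip(frame.temperature, t_min, t_max) - t_min) / (t_max - t_min)
    return np.asarray(colormaps[cmap](norm))[..., :3]
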