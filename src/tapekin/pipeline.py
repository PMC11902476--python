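"""Offline time-series conditioning: filtering, resampling, exclusion masks
and drift adjustments for angle streams.

All filters are zero-phase (forward-backward) since the pipeline targets
recorded trials, which doubles the effective order; causal real-time
variants are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .model import AnchorAngles

__all__ = [
    "FrameMask",
    "lowpass",
    "resample_align",
    "exclude_frames",
    "clamp_pitch",
    "detrend_highpass",
    "condition_imu_angles",
]

#: high-pass cutoffs that remove slow drift without touching the movement band
DETREND_CUTOFF_HZ = {"pitch": 0.001, "roll": 0.01}

REASON_NONE = "NONE"
REASON_FOOT_OFF = "FOOT_OFF"
REASON_BOTH_FEET = "BOTH_FEET_SAME_TAPE"


@dataclass
class FrameMask:
    """Per-frame exclusion mask with reasons."""

    excluded: np.ndarray  # bool
    reason: np.ndarray  # str, REASON_NONE where not excluded

    def __post_init__(self) -> None:
        self.excluded = np.asarray(self.excluded, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=object)
        if self.excluded.shape != self.reason.shape:
            raise ValueError("excluded/reason shape mismatch")
        if np.any(self.excluded != (self.reason != REASON_NONE)):
            raise ValueError("reason must be NONE exactly where not excluded")

    def __len__(self) -> int:
        return len(self.excluded)


def lowpass(series: np.ndarray, fs: float, cutoff_hz: float = 100.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth low-pass (DC gain 1)."""
    x = np.asarray(series, dtype=float)
    if cutoff_hz >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist ({fs / 2} Hz)")
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, x, axis=-1)


def resample_align(
    time_a: np.ndarray,
    series_a: np.ndarray,
    time_b: np.ndarray,
    series_b: np.ndarray,
    target_hz: float = 200.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate two streams onto one shared grid over their overlap.

    Returns ``(t, a, b)``; 2-D inputs are interpolated column-wise.
    """
    ta = np.asarray(time_a, dtype=float)
    tb = np.asarray(time_b, dtype=float)
    start = max(ta[0], tb[0])
    stop = min(ta[-1], tb[-1])
    if stop <= start:
        raise ValueError("streams have no temporal overlap")
    n = int(np.floor((stop - start) * target_hz)) + 1
    t = start + np.arange(n) / target_hz

    def interp(src_t, src):
        src = np.asarray(src, dtype=float)
        if src.ndim == 1:
            return np.interp(t, src_t, src)
        return np.column_stack([np.interp(t, src_t, col) for col in src.T])

    return t, interp(ta, series_a), interp(tb, series_b)


def exclude_frames(
    foot_center_z: np.ndarray,
    tape_center_z: np.ndarray,
    threshold_mm: float = 70.0,
    both_feet_same_tape: np.ndarray | None = None,
) -> FrameMask:
    """Flag frames where the foot is (nearly) off the tape.

    A frame is excluded when the foot center is at least ``threshold_mm``
    above the tape center (inclusive comparison), or when both feet are on
    the same tape.
    """
    foot = np.asarray(foot_center_z, dtype=float)
    tape = np.asarray(tape_center_z, dtype=float)
    off = (foot - tape) >= threshold_mm
    reason = np.full(foot.shape, REASON_NONE, dtype=object)
    reason[off] = REASON_FOOT_OFF
    if both_feet_same_tape is not None:
        both = np.asarray(both_feet_same_tape, dtype=bool)
        reason[both & ~off] = REASON_BOTH_FEET
        off = off | both
    return FrameMask(excluded=off, reason=reason)


def clamp_pitch(series: np.ndarray, mode: str = "clamp") -> np.ndarray:
    """Drift adjustment for normalized pitch, which cannot go negative.

    ``mode="clamp"`` sets negative samples to zero (positive samples are
    untouched); ``mode="shift"`` raises the whole series so its minimum is
    zero.  Neither mode is canonical; clamp is the default.
    """
    x = np.asarray(series, dtype=float)
    if mode == "clamp":
        return np.maximum(x, 0.0)
    if mode == "shift":
        lo = np.min(x)
        return x - lo if lo < 0 else x.copy()
    raise ValueError(f"unknown mode {mode!r}; expected 'clamp' or 'shift'")


def detrend_highpass(series: np.ndarray, fs: float, channel: str = "pitch", order: int = 3) -> np.ndarray:
    """Zero-phase high-pass removing slow sensor drift.

    The cutoff depends on the channel: 0.001 Hz for pitch, 0.01 Hz for
    roll.  Note that on recordings much shorter than the cutoff period the
    attenuation of a constant offset is only partial.
    """
    if channel not in DETREND_CUTOFF_HZ:
        raise ValueError(f"channel must be one of {sorted(DETREND_CUTOFF_HZ)}")
    x = np.asarray(series, dtype=float)
    sos = butter(order, DETREND_CUTOFF_HZ[channel], btype="high", fs=fs, output="sos")
    # maximal odd-extension padding: the filter time constant is comparable
    # to typical trial lengths, so the default padlen leaves edge transients
    return sosfiltfilt(sos, x, axis=-1, padlen=max(x.shape[-1] - 2, 0))


def condition_imu_angles(
    angles: AnchorAngles,
    *,
    clamp: bool = True,
    clamp_mode: str = "clamp",
    detrend: bool = False,
) -> AnchorAngles:
    """Apply the standard IMU drift adjustments to an angle series."""
    out = angles.copy()
    if detrend:
        t = out.time
        fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        for end in ("back", "front"):
            setattr(out, f"pitch_{end}", detrend_highpass(getattr(out, f"pitch_{end}"), fs, "pitch"))
            setattr(out, f"roll_{end}", detrend_highpass(getattr(out, f"roll_{end}"), fs, "roll"))
    if clamp:
        for end in ("back", "front"):
            setattr(out, f"pitch_{end}", clamp_pitch(getattr(out, f"pitch_{end}"), clamp_mode))
    return out
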