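"""Inverse kinematic model of a loaded tape suspended between two anchors.

The tape is treated as an ideal rope: it can only carry tension, so under a
point load it forms two straight segments meeting at the load.  The pitch
angles measured in the tape sections adjacent to the two anchors therefore
determine the load point in the sagittal plane (longitudinal position and
vertical displacement) by intersecting the two anchor rays.  The identical
construction in the horizontal plane maps the two yaw angles to the lateral
displacement.  Roll at the load is extrapolated from the roll measured in
the anchor sections under a piecewise-linear torsion profile in which the
spring segments next to the anchors may twist at a different rate than the
tape itself.

Angle inputs are *normalized*: front and back pitch are both positive when
the tape is displaced downward, and front and back yaw are both positive
when the tape is displaced toward +Y.  In the physical device frame the
front-sensor pitch and yaw have the opposite sign; the ingestion layer
(:func:`tapekin.sections.anchor_angles`) performs that flip.

Units are millimetres, degrees and seconds throughout the public API.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import IntFlag
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "DeviceGeometry",
    "ModelParams",
    "AnchorAngles",
    "TapeEstimate",
    "Flag",
    "CalibrationError",
    "estimate_sagittal",
    "estimate_transversal",
    "apply_segment_correction",
    "segment_ratio_from_foot_length",
    "predict_roll",
    "estimate_kinematics",
    "quality_flags",
    "calibrate",
]

ROLL_VARIANTS = ("RM", "RS", "RWS", "RA")


class CalibrationError(ValueError):
    """Raised when calibration frames do not excite the targeted parameter."""


class Flag(IntFlag):
    """Per-frame quality flags (bitmask)."""

    NONE = 0
    #: small-angle guard fired in the sagittal (pitch) plane
    LOW_LOAD = 1
    #: small-angle guard fired in the transversal (yaw) plane
    LOW_LOAD_TRANSVERSAL = 2
    #: pitch angles with opposite signs -- the anchor rays do not intersect
    #: below the tape; output is non-numeric
    NO_INTERSECTION = 4
    #: yaw angles with opposite signs
    NO_INTERSECTION_TRANSVERSAL = 8
    #: pitch- and yaw-based longitudinal positions disagree while both loaded
    XZ_XY_DISCREPANCY = 16
    #: frame-to-frame longitudinal jump larger than a foot without lift-off
    TEMPORAL_JUMP = 32


def _flag_names(mask: int) -> set[str]:
    return {f.name for f in Flag if f != Flag.NONE and mask & f}


@dataclass(frozen=True)
class DeviceGeometry:
    """Static constants of one tape.

    Attributes
    ----------
    span_L:
        Anchor-to-anchor rest length in mm.
    spring_length:
        Unloaded length of the spring segment at each anchor, mm.
    sensor_section_end:
        Distance from the anchor to the inner boundary of the instrumented
        (sensor) section, mm.
    tape_width:
        Width of the tape, mm.
    """

    span_L: float = 1726.0
    spring_length: float = 200.0
    sensor_section_end: float = 163.0
    tape_width: float = 200.0

    def __post_init__(self) -> None:
        if not self.span_L > 0:
            raise ValueError("span_L must be positive")
        if not 0 < self.spring_length < self.span_L / 2:
            raise ValueError("spring_length must be in (0, span_L/2)")
        if not 0 < self.sensor_section_end <= self.span_L / 2:
            raise ValueError("sensor_section_end must be in (0, span_L/2]")
        if not self.tape_width > 0:
            raise ValueError("tape_width must be positive")

    @property
    def anchor_x(self) -> tuple[float, float]:
        """Longitudinal anchor coordinates (back, front), symmetric about 0."""
        return (-self.span_L / 2.0, self.span_L / 2.0)


def segment_ratio_from_foot_length(flat_length: float, span_L: float) -> float:
    """Geometric depth-correction ratio for a flat foot segment.

    A flat contact segment of length ``flat_length`` centered on the tape
    lowers the tape by less than the ray-intersection model predicts.  By
    similar triangles the true-depth / predicted-depth ratio is
    ``1 - flat_length / span_L``, independent of the depth itself.
    """
    if not 0 <= flat_length < span_L:
        raise ValueError("flat_length must be in [0, span_L)")
    return 1.0 - flat_length / span_L


@dataclass(frozen=True)
class ModelParams:
    """Tunable model parameters.

    ``segment_ratio`` scales the raw vertical displacement to account for
    the finite foot contact length (default 0.85, the geometric value for a
    260 mm flat segment on a 1726 mm span).  ``spring_coeff`` is the twist
    rate of the spring segment expressed as a multiple of the tape's twist
    rate; no universal value exists, so it defaults to ``None`` and should
    be obtained from :func:`calibrate` (``None`` behaves as 1.0, which
    reduces the spring-corrected roll variants to the uncorrected one, and
    triggers a warning on first use).
    """

    segment_ratio: float = 0.85
    spring_coeff: float | None = None
    small_angle_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.segment_ratio <= 1:
            raise ValueError("segment_ratio must be in (0, 1]")
        if self.spring_coeff is not None and not self.spring_coeff > 0:
            raise ValueError("spring_coeff must be positive")
        if self.small_angle_threshold < 0:
            raise ValueError("small_angle_threshold must be >= 0")

    def effective_spring_coeff(self, warn: bool = True) -> float:
        if self.spring_coeff is None:
            if warn:
                warnings.warn(
                    "spring_coeff is uncalibrated; using 1.0, which reduces the "
                    "spring-corrected roll variants (RS/RWS) to the linear one (RM). "
                    "Run calibrate() on roll-only recordings to set it.",
                    stacklevel=3,
                )
            return 1.0
        return self.spring_coeff


@dataclass
class AnchorAngles:
    """Normalized per-frame angles measured at the two anchor sections.

    All fields are 1-D arrays of equal length (a single frame is a length-1
    series).  Pitch and yaw are sign-normalized as described in the module
    docstring; roll keeps its physical sign at both ends.
    """

    time: np.ndarray
    pitch_front: np.ndarray
    pitch_back: np.ndarray
    yaw_front: np.ndarray
    yaw_back: np.ndarray
    roll_front: np.ndarray
    roll_back: np.ndarray

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        n = len(self.time)
        for name in self.__dataclass_fields__:
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")
        for name in ("pitch_front", "pitch_back", "yaw_front", "yaw_back", "roll_front", "roll_back"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name!r}")

    def __len__(self) -> int:
        return len(self.time)

    def copy(self) -> "AnchorAngles":
        return AnchorAngles(**{k: getattr(self, k).copy() for k in self.__dataclass_fields__})

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per (time, end)."""
        rows = []
        for end in ("back", "front"):
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": self.time,
                        "end": end,
                        "roll_deg": getattr(self, f"roll_{end}"),
                        "pitch_deg": getattr(self, f"pitch_{end}"),
                        "yaw_deg": getattr(self, f"yaw_{end}"),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True).sort_values(["time_s", "end"], ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnchorAngles":
        back = df[df["end"] == "back"].sort_values("time_s")
        front = df[df["end"] == "front"].sort_values("time_s")
        if len(back) != len(front):
            raise ValueError("unbalanced front/back rows")
        return cls(
            time=back["time_s"].to_numpy(),
            pitch_front=front["pitch_deg"].to_numpy(),
            pitch_back=back["pitch_deg"].to_numpy(),
            yaw_front=front["yaw_deg"].to_numpy(),
            yaw_back=back["yaw_deg"].to_numpy(),
            roll_front=front["roll_deg"].to_numpy(),
            roll_back=back["roll_deg"].to_numpy(),
        )


class PlaneEstimate(NamedTuple):
    """Result of a single-plane ray intersection (arrays)."""

    x: np.ndarray
    disp: np.ndarray
    flags: np.ndarray  # int bitmask


def _validate_angles(*angles: np.ndarray) -> None:
    for a in angles:
        if not np.all(np.isfinite(a)):
            raise ValueError("input angles must be finite")
        if np.any(np.abs(a) >= 90.0):
            raise ValueError("|angle| must be < 90 degrees")


def _sagittal_ray(a: np.ndarray, b: np.ndarray, span: float) -> tuple[np.ndarray, np.ndarray]:
    """Ray-intersection form: depth and distance from the back anchor."""
    t = np.cos(a) + np.sin(a) * np.cos(b) / np.sin(b)
    z = -np.sin(a) * span / t
    x_back = np.cos(a) * span / t
    return x_back, z

def _sagittal_trig(a: np.ndarray, b: np.ndarray, span: float) -> tuple[np.ndarray, np.ndarray]:
    """Trigonometric form, algebraically equivalent to the ray form."""
    z = -span / (1.0 / np.tan(a) + 1.0 / np.tan(b))
    x_back = np.abs(z) / np.tan(a)
    return x_back, z


#: tolerance (relative to the span) for agreement of the two formulations
_FORMULATION_RTOL = 1e-9


def _intersect(back_deg, front_deg, span, threshold, *, signed_output):
    """Shared 2-D ray intersection with small-angle guard and sign handling.

    ``back_deg``/``front_deg`` are the normalized angles at the back/front
    anchor.  With ``signed_output=False`` (sagittal plane) both angles must
    be positive for a valid solution and the displacement is <= 0.  With
    ``signed_output=True`` (horizontal plane) a both-negative pair is a
    mirrored valid solution and the displacement carries its sign.
    """
    back = np.atleast_1d(np.asarray(back_deg, dtype=float))
    front = np.atleast_1d(np.asarray(front_deg, dtype=float))
    back, front = np.broadcast_arrays(back, front)
    _validate_angles(back, front)

    flags = np.zeros(back.shape, dtype=np.int64)
    x = np.zeros(back.shape, dtype=float)
    disp = np.zeros(back.shape, dtype=float)

    big = (np.abs(back) >= threshold) & (np.abs(front) >= threshold)
    opposite = big & (np.sign(back) * np.sign(front) < 0)
    if signed_output:
        guard = ~opposite & (np.minimum(np.abs(back), np.abs(front)) < threshold)
        no_int_flag = Flag.NO_INTERSECTION_TRANSVERSAL
        guard_flag = Flag.LOW_LOAD_TRANSVERSAL
    else:
        # strict "<": angles exactly at the threshold are used
        guard = ~opposite & (np.minimum(back, front) < threshold)
        no_int_flag = Flag.NO_INTERSECTION
        guard_flag = Flag.LOW_LOAD

    flags[opposite] |= int(no_int_flag)
    flags[guard] |= int(guard_flag)
    x[opposite] = np.nan
    disp[opposite] = np.nan

    ok = ~opposite & ~guard
    if np.any(ok):
        sign = np.sign(back[ok]) if signed_output else 1.0
        a = np.radians(np.abs(back[ok]))
        b = np.radians(np.abs(front[ok]))
        x_ray, d_ray = _sagittal_ray(a, b, span)
        x_trig, d_trig = _sagittal_trig(a, b, span)
        tol = _FORMULATION_RTOL * span
        if not (np.all(np.abs(x_ray - x_trig) < tol) and np.all(np.abs(d_ray - d_trig) < tol)):
            raise FloatingPointError(
                "ray-intersection and trigonometric formulations disagree beyond tolerance"
            )
        x[ok] = x_ray - span / 2.0  # device frame, origin mid-span
        disp[ok] = d_ray if not signed_output else -sign * d_ray
    return PlaneEstimate(x, disp, flags)


def estimate_sagittal(
    alpha: float | np.ndarray,
    beta: float | np.ndarray,
    geom: DeviceGeometry,
    params: ModelParams | None = None,
) -> PlaneEstimate:
    """Longitudinal position and vertical displacement from the pitch pair.

    ``alpha`` is the normalized pitch at the back anchor (``x = -L/2``) and
    ``beta`` at the front anchor; both are positive when the tape is
    displaced downward.  Returns the longitudinal position in the device
    frame (origin mid-span) and the (non-positive) vertical displacement of
    the inferred load point.  Frames where either angle is below the
    small-angle threshold yield ``(0, 0)`` with :data:`Flag.LOW_LOAD`;
    opposite-sign pairs yield NaN with :data:`Flag.NO_INTERSECTION`.
    """
    params = params or ModelParams()
    return _intersect(
        alpha, beta, geom.span_L, params.small_angle_threshold, signed_output=False
    )


def estimate_transversal(
    yaw_back: float | np.ndarray,
    yaw_front: float | np.ndarray,
    geom: DeviceGeometry,
    params: ModelParams | None = None,
) -> PlaneEstimate:
    """Longitudinal position and lateral displacement from the yaw pair.

    Identical mathematics to :func:`estimate_sagittal` applied in the
    horizontal plane.  Lateral displacement is signed (positive toward +Y);
    a pair of negative yaw angles is the mirror-image solution.  No
    segment-length correction is applied to the lateral output.
    """
    params = params or ModelParams()
    return _intersect(
        yaw_back, yaw_front, geom.span_L, params.small_angle_threshold, signed_output=True
    )


def apply_segment_correction(
    z_disp: float | np.ndarray, params: ModelParams
) -> float | np.ndarray:
    """Scale raw vertical displacement by the foot-segment ratio.

    Only the displacement is corrected; the longitudinal position is left
    untouched.
    """
    return params.segment_ratio * np.asarray(z_disp, dtype=float)


def _effective_twist_length(dist, spring_length, k):
    """Tape-equivalent twist length of the stretch ``[0, dist]`` from an anchor.

    The first ``spring_length`` mm twist at ``k`` times the tape rate, the
    remainder at the tape rate.
    """
    d = np.asarray(dist, dtype=float)
    return k * np.minimum(d, spring_length) + np.maximum(d - spring_length, 0.0)


def _per_anchor_roll_estimates(roll_front, roll_back, x_from_pitch, geom, k):
    """Extrapolate each sensor's roll to the load position.

    The measured roll is the twist accumulated from the anchor to the inner
    sensor boundary; dividing by the effective twist length there and
    multiplying by the effective length to the load gives the per-anchor
    roll estimate at the load.
    """
    half = geom.span_L / 2.0
    d_back = np.asarray(x_from_pitch, dtype=float) + half
    d_front = half - np.asarray(x_from_pitch, dtype=float)
    e_sensor = _effective_twist_length(geom.sensor_section_end, geom.spring_length, k)
    est_back = np.asarray(roll_back, dtype=float) * (
        _effective_twist_length(d_back, geom.spring_length, k) / e_sensor
    )
    est_front = np.asarray(roll_front, dtype=float) * (
        _effective_twist_length(d_front, geom.spring_length, k) / e_sensor
    )
    return est_back, est_front, d_back, d_front


def predict_roll(
    roll_front: float | np.ndarray,
    roll_back: float | np.ndarray,
    x_from_pitch: float | np.ndarray | None,
    geom: DeviceGeometry,
    params: ModelParams,
    variant: str,
) -> np.ndarray:
    """Roll angle of the loaded tape segment, by modeling variant.

    Variants:

    * ``RA`` -- sum of the two measured rolls (position-free).
    * ``RM`` -- linear twist extrapolation from each anchor to the load,
      averaged.
    * ``RS`` -- like RM, with the spring segment twisting at
      ``params.spring_coeff`` times the tape rate.
    * ``RWS`` -- the RS per-anchor estimates combined with linear weights
      favoring the sensor nearer the load.

    ``x_from_pitch`` (device frame) is required for RM/RS/RWS; NaN entries
    propagate to NaN predictions.
    """
    variant = variant.upper()
    if variant not in ROLL_VARIANTS:
        raise ValueError(f"unknown roll variant {variant!r}; expected one of {ROLL_VARIANTS}")
    rf = np.atleast_1d(np.asarray(roll_front, dtype=float))
    rb = np.atleast_1d(np.asarray(roll_back, dtype=float))
    if variant == "RA":
        return rf + rb
    if x_from_pitch is None:
        raise ValueError(f"variant {variant} requires the longitudinal position")
    x = np.atleast_1d(np.asarray(x_from_pitch, dtype=float))
    half = geom.span_L / 2.0
    with np.errstate(invalid="ignore"):
        in_span = (x >= -half) & (x <= half)
    if np.any(~in_span & np.isfinite(x)):
        raise ValueError("x_from_pitch outside the anchor span")

    k = 1.0 if variant == "RM" else params.effective_spring_coeff()
    est_back, est_front, d_back, d_front = _per_anchor_roll_estimates(rf, rb, x, geom, k)
    if variant in ("RM", "RS"):
        return 0.5 * (est_back + est_front)
    # RWS: nearer sensor dominates
    w_back = d_front / geom.span_L
    w_front = d_back / geom.span_L
    return w_back * est_back + w_front * est_front


@dataclass
class TapeEstimate:
    """Per-frame model outputs (arrays aligned with the input series)."""

    time: np.ndarray
    x_from_pitch: np.ndarray
    x_from_yaw: np.ndarray
    y_disp: np.ndarray
    z_disp: np.ndarray
    z_corrected: np.ndarray
    roll_rm: np.ndarray
    roll_rs: np.ndarray
    roll_rws: np.ndarray
    roll_ra: np.ndarray
    flags: np.ndarray

    def __len__(self) -> int:
        return len(self.time)

    def flag_sets(self) -> list[set[str]]:
        return [_flag_names(int(m)) for m in self.flags]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "x_from_pitch_mm": self.x_from_pitch,
                "x_from_yaw_mm": self.x_from_yaw,
                "y_mm": self.y_disp,
                "z_mm": self.z_disp,
                "z_corrected_mm": self.z_corrected,
                "roll_rm_deg": self.roll_rm,
                "roll_rs_deg": self.roll_rs,
                "roll_rws_deg": self.roll_rws,
                "roll_ra_deg": self.roll_ra,
                "flags": self.flags.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TapeEstimate":
        return cls(
            time=df["time_s"].to_numpy(),
            x_from_pitch=df["x_from_pitch_mm"].to_numpy(),
            x_from_yaw=df["x_from_yaw_mm"].to_numpy(),
            y_disp=df["y_mm"].to_numpy(),
            z_disp=df["z_mm"].to_numpy(),
            z_corrected=df["z_corrected_mm"].to_numpy(),
            roll_rm=df["roll_rm_deg"].to_numpy(),
            roll_rs=df["roll_rs_deg"].to_numpy(),
            roll_rws=df["roll_rws_deg"].to_numpy(),
            roll_ra=df["roll_ra_deg"].to_numpy(),
            flags=df["flags"].to_numpy(dtype=np.int64),
        )


def estimate_kinematics(
    angles: AnchorAngles,
    geom: DeviceGeometry,
    params: ModelParams | None = None,
) -> TapeEstimate:
    """Run the full per-frame model over an angle series.

    Produces both longitudinal position estimates, the lateral and vertical
    displacements, the corrected displacement and the four roll variants.
    Roll variants needing a position inherit NaN where the sagittal solution
    is flagged non-numeric; guard frames use the mid-span position.
    """
    params = params or ModelParams()
    sag = estimate_sagittal(angles.pitch_back, angles.pitch_front, geom, params)
    trans = estimate_transversal(angles.yaw_back, angles.yaw_front, geom, params)
    flags = sag.flags | trans.flags
    z_corr = apply_segment_correction(sag.disp, params)
    common = dict(geom=geom, params=params)
    roll = {
        v: predict_roll(angles.roll_front, angles.roll_back, sag.x, variant=v, **common)
        for v in ("RM", "RS", "RWS")
    }
    roll["RA"] = predict_roll(angles.roll_front, angles.roll_back, None, variant="RA", **common)
    return TapeEstimate(
        time=angles.time.copy(),
        x_from_pitch=sag.x,
        x_from_yaw=trans.x,
        y_disp=trans.disp,
        z_disp=sag.disp,
        z_corrected=z_corr,
        roll_rm=roll["RM"],
        roll_rs=roll["RS"],
        roll_rws=roll["RWS"],
        roll_ra=roll["RA"],
        flags=flags,
    )


def quality_flags(
    estimate: TapeEstimate,
    geom: DeviceGeometry,
    *,
    discrepancy_bound_mm: float = 300.0,
    foot_length_mm: float = 300.0,
) -> list[set[str]]:
    """Add heuristic outlier flags to an estimate series (in place).

    * ``XZ_XY_DISCREPANCY``: the two longitudinal estimates differ by more
      than ``discrepancy_bound_mm`` while both planes are loaded.
    * ``TEMPORAL_JUMP``: the pitch-based position jumps by more than a foot
      length between loaded frames with no intervening low-load phase.

    Returns the per-frame flag-name sets after the update.
    """
    flags = estimate.flags
    loaded_sag = (flags & int(Flag.LOW_LOAD | Flag.NO_INTERSECTION)) == 0
    loaded_trans = (flags & int(Flag.LOW_LOAD_TRANSVERSAL | Flag.NO_INTERSECTION_TRANSVERSAL)) == 0
    both = loaded_sag & loaded_trans
    with np.errstate(invalid="ignore"):
        disc = both & (
            np.abs(estimate.x_from_pitch - estimate.x_from_yaw) > discrepancy_bound_mm
        )
    flags[disc] |= int(Flag.XZ_XY_DISCREPANCY)

    last_x = None
    for i in range(len(estimate)):
        if not loaded_sag[i] or not np.isfinite(estimate.x_from_pitch[i]):
            last_x = None  # a lift-off / unloaded phase resets the chain
            continue
        if last_x is not None and abs(estimate.x_from_pitch[i] - last_x) > foot_length_mm:
            flags[i] |= int(Flag.TEMPORAL_JUMP)
        last_x = estimate.x_from_pitch[i]
    return estimate.flag_sets()


def _coerce_calibration_input(frames, truth):
    """Accept either (AnchorAngles, truth-DataFrame) or pairs of
    (AnchorAngles, TapeShape)."""
    if truth is not None:
        return frames, truth
    rows = []
    series: list[AnchorAngles] = []
    for angles, shape in frames:
        series.append(angles)
        rows.append(
            {
                "x_mm": shape.foot_x,
                "z_mm": float(np.min(shape.polyline[:, 2])),
                "roll_deg": shape.true_foot_roll,
            }
        )
    merged = AnchorAngles(
        time=np.concatenate([a.time for a in series]),
        pitch_front=np.concatenate([a.pitch_front for a in series]),
        pitch_back=np.concatenate([a.pitch_back for a in series]),
        yaw_front=np.concatenate([a.yaw_front for a in series]),
        yaw_back=np.concatenate([a.yaw_back for a in series]),
        roll_front=np.concatenate([a.roll_front for a in series]),
        roll_back=np.concatenate([a.roll_back for a in series]),
    )
    return merged, pd.DataFrame(rows)


def calibrate(
    frames: AnchorAngles | Sequence[tuple],
    targets: Iterable[str],
    geom: DeviceGeometry,
    params: ModelParams | None = None,
    truth: pd.DataFrame | None = None,
) -> ModelParams:
    """Least-squares estimation of model parameters from reference frames.

    ``frames`` is either an :class:`AnchorAngles` series (with ``truth`` a
    frame-aligned DataFrame carrying ``x_mm``, ``z_mm``, ``roll_deg``) or a
    sequence of ``(AnchorAngles, TapeShape)`` pairs.  ``targets`` selects
    ``"segment_ratio"`` (fit on vertical-only excitation) and/or
    ``"spring_coeff"`` (fit on roll-only excitation).  Returns an updated
    :class:`ModelParams`.
    """
    params = params or ModelParams()
    targets = set(targets)
    unknown = targets - {"segment_ratio", "spring_coeff"}
    if unknown:
        raise ValueError(f"unknown calibration targets: {sorted(unknown)}")
    angles, truth_df = _coerce_calibration_input(frames, truth)
    if len(angles) < 10:
        raise CalibrationError("calibration requires at least 10 frames")
    if len(truth_df) != len(angles):
        raise CalibrationError("truth length does not match angle frames")

    updates: dict[str, float] = {}
    if "segment_ratio" in targets:
        sag = estimate_sagittal(angles.pitch_back, angles.pitch_front, geom, params)
        z_model = sag.disp
        z_true = truth_df["z_mm"].to_numpy(dtype=float)
        use = np.isfinite(z_model) & (np.abs(z_model) > 1.0)
        if use.sum() < 10 or np.sum(z_model[use] ** 2) < 1e-6:
            raise CalibrationError("insufficient vertical excitation for segment_ratio")
        ratio = float(np.sum(z_model[use] * z_true[use]) / np.sum(z_model[use] ** 2))
        if not 0 < ratio <= 1:
            raise CalibrationError(f"fitted segment_ratio {ratio:.3f} outside (0, 1]")
        updates["segment_ratio"] = ratio

    if "spring_coeff" in targets:
        roll_true = truth_df["roll_deg"].to_numpy(dtype=float)
        x_true = truth_df["x_mm"].to_numpy(dtype=float)
        if np.max(np.abs(roll_true)) < 0.5:
            raise CalibrationError("insufficient roll excitation for spring_coeff")

        rf, rb = angles.roll_front, angles.roll_back

        def sse(log_k: float) -> float:
            eb, ef, _, _ = _per_anchor_roll_estimates(rf, rb, x_true, geom, np.exp(log_k))
            pred = 0.5 * (eb + ef)
            return float(np.sum((pred - roll_true) ** 2))

        res = minimize_scalar(sse, bounds=(np.log(1e-2), np.log(1e2)), method="bounded")
        if not res.success:
            raise CalibrationError("spring_coeff optimisation failed")
        updates["spring_coeff"] = float(np.exp(res.x))

    return replace(params, **updates)
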