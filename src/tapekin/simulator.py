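"""Forward geometric simulator of a loaded tape between two fixed anchors.

The tape is an ideal rope: straight from each anchor to the contact span of
the load (a point or a flat foot segment), with lateral displacement handled
analogously in the horizontal plane and a piecewise-linear torsion profile
whose rate is multiplied by a spring coefficient inside the spring segments.
The simulator emits ground-truth shapes, per-section angles, edge-marker
clouds and clean/degraded angle streams, and serves as the oracle for the
inverse model.

No dynamics are modeled: no mass, tension, oscillation or catenary sag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.spatial.transform import Rotation

from .model import AnchorAngles, DeviceGeometry, _effective_twist_length
from .sections import N_SECTIONS, SectionLayout

__all__ = [
    "FootLoad",
    "TapeShape",
    "DriftSpec",
    "TrialResult",
    "simulate_static",
    "simulate_trial",
    "add_imu_drift",
]


@dataclass(frozen=True)
class FootLoad:
    """A single load state: contact position, depth and orientation.

    ``depth`` is the true lowest-point displacement (>= 0, downward);
    ``flat_length`` is the length of the flat contact segment (0 for a point
    load).  ``airborne`` marks the load as lifted off the tape.
    """

    x_center: float = 0.0
    depth: float = 0.0
    flat_length: float = 0.0
    y_offset: float = 0.0
    foot_roll: float = 0.0
    airborne: bool = False

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.flat_length < 0:
            raise ValueError("flat_length must be >= 0")
        if self.airborne and self.depth != 0:
            raise ValueError("airborne load cannot have depth > 0")

    def validate_span(self, geom: DeviceGeometry) -> None:
        if abs(self.x_center) + self.flat_length / 2.0 >= geom.span_L / 2.0:
            raise ValueError("load (incl. flat segment) must lie strictly inside the span")


@dataclass
class TapeShape:
    """Ground-truth deformed state of one tape."""

    polyline: np.ndarray  # (n, 3) anchor-to-anchor, includes contact vertices
    section_rolls: np.ndarray  # physical roll per section (7,)
    section_pitches: np.ndarray
    section_yaws: np.ndarray
    true_foot_roll: float
    foot_x: float
    markers: pd.DataFrame | None = None  # long format, None unless requested

    @property
    def lowest_point(self) -> float:
        return float(np.min(self.polyline[:, 2]))


@dataclass(frozen=True)
class DriftSpec:
    """Degradation applied to an angle stream to emulate IMU output.

    Pitch drifts one-sidedly (linear ramp, normally negative-going on the
    normalized angle), yaw performs an unbiased random walk, roll is stable
    up to white noise.  ``end_scale`` scales the pitch ramp per sensor
    (back, front) since physical units drift at different rates.
    """

    pitch_drift_rate: float = -0.05  # deg/s, one-sided
    yaw_drift_rate: float = 0.02  # deg/sqrt(s), random-walk step scale
    roll_drift_rate: float = 0.0  # deg/s, ~0 in practice
    noise_sigma: float = 0.05  # deg, white noise on all channels
    seed: int = 0
    end_scale: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _lateral_state(u: float, d_foot: float, y: float, spring_len: float, m: float):
    """Lateral offset and slope at distance ``u`` from an anchor.

    The straight-line path to the contact point is kinked at the spring
    boundary when the spring's lateral compliance multiplier ``m`` differs
    from 1; the slope inside the spring is ``m`` times the tape slope.
    """
    if y == 0.0 or d_foot <= 0:
        return 0.0, 0.0
    eff = m * min(d_foot, spring_len) + max(d_foot - spring_len, 0.0)
    t = y / eff
    if u <= spring_len:
        return m * t * u, m * t
    return m * t * spring_len + t * (u - spring_len), t


def _twist_at(
    x: float,
    x_start: float,
    x_end: float,
    foot_roll: float,
    geom: DeviceGeometry,
    k: float,
) -> float:
    """Torsion angle of the tape at longitudinal position ``x``.

    Linear in effective twist length from the nearer anchor up to the foot
    contact span, constant (= foot roll) underneath the foot.
    """
    if foot_roll == 0.0:
        return 0.0
    half = geom.span_L / 2.0
    if x <= x_start:
        u, d = x + half, x_start + half
    elif x >= x_end:
        u, d = half - x, half - x_end
    else:
        return foot_roll
    if d <= 0:
        return foot_roll
    return foot_roll * float(
        _effective_twist_length(u, geom.spring_length, k)
        / _effective_twist_length(d, geom.spring_length, k)
    )


def _vertical_state(x: float, x_start: float, x_end: float, depth: float, half: float):
    """Vertical offset and slope dz/dx at longitudinal position ``x``."""
    if depth == 0.0:
        return 0.0, 0.0
    if x <= x_start:
        d = x_start + half
        return -depth * (x + half) / d, -depth / d
    if x >= x_end:
        d = half - x_end
        return -depth * (half - x) / d, depth / d
    return -depth, 0.0


def _build_markers(layout: SectionLayout, local_state, time_s: float = 0.0) -> pd.DataFrame:
    """Place edge markers using the local tape pose at each marker station.

    Each station carries a cross-section rotated by the local roll/pitch/yaw;
    the stations adjacent to the anchors are rigidly hinged at the anchor
    point (the tape is inextensible), so the anchor-section reconstruction
    via the Kabsch fit is exact.  Interior stations sit on the centerline.
    """
    rest = layout.rest_positions()
    anchor_back, anchor_front = layout.anchor_points()
    rows: dict[str, np.ndarray] = {}
    for lab, ref in rest.items():
        roll, pitch, yaw, center = local_state(ref[0])
        rot = Rotation.from_euler("XYZ", [roll, pitch, yaw], degrees=True)
        offset = np.array([0.0, ref[1], 0.0])
        if lab in ("i2", "o2"):
            base = anchor_back + rot.apply(ref - anchor_back - offset)
        elif lab in ("i7", "o7"):
            base = anchor_front + rot.apply(ref - anchor_front - offset)
        else:
            base = center
        rows[lab] = base + rot.apply(offset)
    return pd.DataFrame(
        [
            {"time_s": time_s, "label": lab, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
            for lab, p in sorted(rows.items())
        ]
    )


def simulate_static(
    load: FootLoad,
    geom: DeviceGeometry,
    spring_coeff: float = 1.0,
    *,
    yaw_spring_coeff: float = 1.0,
    layout: SectionLayout | None = None,
    with_markers: bool = False,
    time_s: float = 0.0,
) -> tuple[TapeShape, AnchorAngles]:
    """Exact deformed shape and normalized anchor angles for one load state.

    The returned angles follow the model's normalization (front pitch/yaw
    sign-flipped relative to the physical frame); the shape carries the
    physical per-section angles used for marker generation.
    """
    load.validate_span(geom)
    layout = layout or SectionLayout.default(geom)
    half = geom.span_L / 2.0
    zeros7 = np.zeros(N_SECTIONS)

    if load.airborne:
        polyline = np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]])
        shape = TapeShape(polyline, zeros7, zeros7.copy(), zeros7.copy(), 0.0, load.x_center)
        if with_markers:
            rest_state = lambda x: (0.0, 0.0, 0.0, np.array([x, 0.0, 0.0]))  # noqa: E731
            shape.markers = _build_markers(layout, rest_state, time_s)
        angles = AnchorAngles(time_s, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        return shape, angles

    x_start = load.x_center - load.flat_length / 2.0
    x_end = load.x_center + load.flat_length / 2.0
    d_back = x_start + half
    d_front = half - x_end

    alpha = np.degrees(np.arctan2(load.depth, d_back))  # back anchor, normalized
    beta = np.degrees(np.arctan2(load.depth, d_front))  # front anchor, normalized

    y_back_sensor, slope_back = _lateral_state(
        geom.sensor_section_end, d_back, load.y_offset, geom.spring_length, yaw_spring_coeff
    )
    _, slope_front = _lateral_state(
        geom.sensor_section_end, d_front, load.y_offset, geom.spring_length, yaw_spring_coeff
    )
    yaw_back = np.degrees(np.arctan(slope_back))
    yaw_front = np.degrees(np.arctan(slope_front))  # normalized: positive toward +Y

    roll_back = _twist_at(-half + geom.sensor_section_end, x_start, x_end, load.foot_roll, geom, spring_coeff)
    roll_front = _twist_at(half - geom.sensor_section_end, x_start, x_end, load.foot_roll, geom, spring_coeff)

    def local_state(xq: float):
        """Local (roll, pitch, yaw, center) of the tape at position ``xq``."""
        z_val, dz = _vertical_state(xq, x_start, x_end, load.depth, half)
        if x_start < xq < x_end:
            y_val, dy = load.y_offset, 0.0
        elif xq <= x_start:
            y_val, dy = _lateral_state(
                xq + half, d_back, load.y_offset, geom.spring_length, yaw_spring_coeff
            )
        else:
            y_val, dy_mag = _lateral_state(
                half - xq, d_front, load.y_offset, geom.spring_length, yaw_spring_coeff
            )
            dy = -dy_mag
        roll = _twist_at(xq, x_start, x_end, load.foot_roll, geom, spring_coeff)
        pitch = np.degrees(np.arctan(-dz))
        yaw = np.degrees(np.arctan(dy))
        return roll, pitch, yaw, np.array([xq, y_val, z_val])

    # per-section physical angles, evaluated at the marker station for the
    # anchor sections and at the section midpoint otherwise
    rolls, pitches, yaws = zeros7.copy(), zeros7.copy(), zeros7.copy()
    for j in range(N_SECTIONS):
        if j == 0:
            x_rep = layout.border_x[1]
        elif j == N_SECTIONS - 1:
            x_rep = layout.border_x[N_SECTIONS - 1]
        else:
            x_rep = 0.5 * (layout.border_x[j] + layout.border_x[j + 1])
        rolls[j], pitches[j], yaws[j], _ = local_state(x_rep)

    if load.flat_length > 0:
        polyline = np.array(
            [
                [-half, 0.0, 0.0],
                [x_start, load.y_offset, -load.depth],
                [x_end, load.y_offset, -load.depth],
                [half, 0.0, 0.0],
            ]
        )
    else:
        polyline = np.array(
            [[-half, 0.0, 0.0], [load.x_center, load.y_offset, -load.depth], [half, 0.0, 0.0]]
        )

    shape = TapeShape(polyline, rolls, pitches, yaws, load.foot_roll, load.x_center)
    if with_markers:
        shape.markers = _build_markers(layout, local_state, time_s)
    angles = AnchorAngles(
        time=time_s,
        pitch_front=beta,
        pitch_back=alpha,
        yaw_front=yaw_front,
        yaw_back=yaw_back,
        roll_front=roll_front,
        roll_back=roll_back,
    )
    return shape, angles


@dataclass
class TrialResult:
    """Bundle of synchronized streams produced by :func:`simulate_trial`."""

    time: np.ndarray
    truth: pd.DataFrame
    angles_mocap: AnchorAngles
    angles_imu: AnchorAngles
    markers: pd.DataFrame | None = None


def _interp_channel(kf_t: np.ndarray, values: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Monotone cubic keyframe interpolation (no overshoot)."""
    if len(kf_t) == 1:
        return np.full_like(t, values[0])
    return PchipInterpolator(kf_t, values)(t)


def simulate_trial(
    script: Sequence[tuple[float, FootLoad]],
    rate: float,
    geom: DeviceGeometry,
    spring_coeff: float = 1.0,
    noise: DriftSpec | None = None,
    *,
    yaw_spring_coeff: float = 1.0,
    with_markers: bool = False,
    lift_mm: float = 150.0,
) -> TrialResult:
    """Sample a keyframed load script into synchronized truth/angle streams.

    Keyframes are interpolated with a monotone cubic in depth, position and
    roll; the ``airborne`` flag switches stepwise (previous keyframe holds)
    and forces zero depth.  The motion-capture stream is exact; the IMU
    stream is the same angles degraded by :func:`add_imu_drift` when
    ``noise`` is given.  Deterministic under a fixed ``noise.seed``.
    """
    if len(script) == 0:
        raise ValueError("empty trial script")
    if rate <= 0:
        raise ValueError("rate must be positive")
    kf_t = np.array([t for t, _ in script], dtype=float)
    if np.any(np.diff(kf_t) <= 0):
        raise ValueError("keyframes must be strictly time-ordered")
    loads = [lo for _, lo in script]

    t0, t1 = kf_t[0], kf_t[-1]
    n = max(int(round((t1 - t0) * rate)), 1)
    t = t0 + np.arange(n) / rate

    x = _interp_channel(kf_t, np.array([lo.x_center for lo in loads]), t)
    depth = np.clip(_interp_channel(kf_t, np.array([lo.depth for lo in loads]), t), 0.0, None)
    flat = np.clip(_interp_channel(kf_t, np.array([lo.flat_length for lo in loads]), t), 0.0, None)
    y = _interp_channel(kf_t, np.array([lo.y_offset for lo in loads]), t)
    roll = _interp_channel(kf_t, np.array([lo.foot_roll for lo in loads]), t)
    air_kf = np.array([lo.airborne for lo in loads], dtype=bool)
    air = air_kf[np.clip(np.searchsorted(kf_t, t, side="right") - 1, 0, len(kf_t) - 1)]

    cols = {k: np.zeros(n) for k in ("pitch_front", "pitch_back", "yaw_front", "yaw_back", "roll_front", "roll_back")}
    marker_frames: list[pd.DataFrame] = []
    layout = SectionLayout.default(geom)
    for i in range(n):
        load = FootLoad(
            x_center=float(x[i]),
            depth=0.0 if air[i] else float(depth[i]),
            flat_length=float(flat[i]),
            y_offset=0.0 if air[i] else float(y[i]),
            foot_roll=0.0 if air[i] else float(roll[i]),
            airborne=bool(air[i]),
        )
        shape, ang = simulate_static(
            load,
            geom,
            spring_coeff,
            yaw_spring_coeff=yaw_spring_coeff,
            layout=layout,
            with_markers=with_markers,
            time_s=float(t[i]),
        )
        for key in cols:
            cols[key][i] = getattr(ang, key)[0]
        if with_markers:
            marker_frames.append(shape.markers)

    truth = pd.DataFrame(
        {
            "time_s": t,
            "x_mm": x,
            "y_mm": np.where(air, 0.0, y),
            "z_mm": np.where(air, 0.0, -depth),
            "roll_deg": np.where(air, 0.0, roll),
            "airborne": air,
            # center of the foot segment: on the tape when loaded, lifted otherwise
            "foot_z_mm": np.where(air, lift_mm, -depth),
        }
    )
    mocap = AnchorAngles(time=t, **cols)
    imu = add_imu_drift(mocap, noise) if noise is not None else mocap.copy()
    markers = pd.concat(marker_frames, ignore_index=True) if with_markers else None
    return TrialResult(time=t, truth=truth, angles_mocap=mocap, angles_imu=imu, markers=markers)


def add_imu_drift(angles: AnchorAngles, spec: DriftSpec) -> AnchorAngles:
    """Degrade a clean angle stream into an IMU-like stream.

    Pitch gains a one-sided linear ramp, yaw a seeded unbiased random walk,
    roll only a (configurable, default zero) ramp; all channels gain white
    Gaussian noise.  Reproducible from ``spec.seed``.
    """
    t = angles.time
    if np.any(np.diff(t) < 0):
        raise ValueError("angle series must be time-ordered")
    rng = np.random.default_rng(spec.seed)
    rel = t - t[0]
    dt = np.diff(t, prepend=t[0])
    out = angles.copy()
    for end, scale in zip(("back", "front"), spec.end_scale):
        walk = np.cumsum(rng.normal(0.0, 1.0, len(t)) * spec.yaw_drift_rate * np.sqrt(dt))
        noise = {ch: rng.normal(0.0, spec.noise_sigma, len(t)) if spec.noise_sigma > 0 else 0.0
                 for ch in ("pitch", "yaw", "roll")}
        pitch = getattr(out, f"pitch_{end}")
        pitch += spec.pitch_drift_rate * scale * rel + noise["pitch"]
        yaw = getattr(out, f"yaw_{end}")
        yaw += walk + noise["yaw"]
        roll = getattr(out, f"roll_{end}")
        roll += spec.roll_drift_rate * rel + noise["roll"]
    return out
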