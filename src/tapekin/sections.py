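"""Rigid-body reconstruction of tape sections from marker trajectories.

A tape carries eleven reflective markers along its inner and outer edges.
Consecutive marker stations split the tape into seven sections; each section
is treated as a rigid body whose rotation relative to the rest pose is
recovered with the Kabsch algorithm and decomposed into Tait-Bryan angles
(XYZ intrinsic: roll about X, then pitch about Y, then yaw about Z).  The
front and back sections have only one marker station, so the fixed anchor
coordinates are appended as an extra matched point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .model import AnchorAngles, DeviceGeometry

__all__ = [
    "DegenerateGeometryError",
    "GimbalWarning",
    "SectionLayout",
    "kabsch_transform",
    "taitbryan_xyz",
    "rotation_from_taitbryan",
    "section_angles",
    "anchor_angles",
    "rest_alignment",
]

N_SECTIONS = 7


class DegenerateGeometryError(ValueError):
    """Marker configuration does not determine a rotation (collinear/too few)."""


class GimbalWarning(UserWarning):
    """Pitch close to +-90 degrees: roll/yaw decomposition is ill-conditioned."""


@dataclass(frozen=True)
class SectionLayout:
    """Marker stations and section boundaries of one tape.

    ``border_x`` holds the 8 longitudinal section boundaries including the
    two anchors.  Marker stations sit at the six interior boundaries; each
    carries an outer-edge marker (``o2``..``o7``), the outermost four also
    carry inner-edge markers (``i2``, ``i3``, ``i6``, ``i7``), and a single
    shared inner-edge marker ``imid`` sits at mid-span, belonging to the
    marker pairs on both sides.  This yields eleven markers, three of which
    define the middle section and four each of the others; the front and
    back sections combine their marker pair with the anchor point.
    """

    border_x: tuple[float, ...]
    tape_width: float
    section_labels: tuple[tuple[str, ...], ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.border_x) != N_SECTIONS + 1:
            raise ValueError("expected 8 section boundaries (incl. anchors)")
        if list(self.border_x) != sorted(self.border_x):
            raise ValueError("section boundaries must be increasing")
        labels = (
            ("i2", "o2"),
            ("i2", "o2", "i3", "o3"),
            ("i3", "o3", "o4", "imid"),
            ("o4", "imid", "o5"),
            ("imid", "o5", "i6", "o6"),
            ("i6", "o6", "i7", "o7"),
            ("i7", "o7"),
        )
        object.__setattr__(self, "section_labels", labels)

    @classmethod
    def default(cls, geom: DeviceGeometry) -> "SectionLayout":
        """Layout derived from the device geometry.

        The first interior boundary sits at ``sensor_section_end`` from each
        anchor; the remaining boundaries are placed symmetrically.
        """
        half = geom.span_L / 2.0
        s = geom.sensor_section_end
        b2 = -half + s
        b3 = b2 + (half - s) * 0.45
        b4 = b2 + (half - s) * 0.82
        return cls(
            border_x=(-half, b2, b3, b4, -b4, -b3, -b2, half),
            tape_width=geom.tape_width,
        )

    def rest_positions(self) -> dict[str, np.ndarray]:
        """Nominal marker coordinates of the unloaded tape (z = 0)."""
        w = self.tape_width / 2.0
        b = self.border_x
        pos = {"imid": np.array([0.0, w, 0.0])}
        for j, station in enumerate(b[1:7], start=2):
            pos[f"o{j}"] = np.array([station, -w, 0.0])
            if j in (2, 3, 6, 7):
                pos[f"i{j}"] = np.array([station, w, 0.0])
        return pos

    def anchor_points(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([self.border_x[0], 0.0, 0.0]),
            np.array([self.border_x[-1], 0.0, 0.0]),
        )


def kabsch_transform(
    ref_points: np.ndarray, obs_points: np.ndarray, weights: np.ndarray | None = None
) -> tuple[Rotation, np.ndarray, float]:
    """Best-fit proper rotation and translation mapping ``ref`` onto ``obs``.

    Returns ``(rotation, translation, rmsd)`` minimizing the RMSD of
    ``rotation.apply(ref) + translation`` against ``obs``.  The rotation is
    always proper (determinant +1), even for reflected observations.
    """
    ref = np.asarray(ref_points, dtype=float)
    obs = np.asarray(obs_points, dtype=float)
    if ref.shape != obs.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and obs must be matched (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise DegenerateGeometryError("at least 3 matched points are required")
    ref_mean = ref.mean(axis=0)
    obs_mean = obs.mean(axis=0)
    ref_c = ref - ref_mean
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("reference points are collinear")
    w = None if weights is None else np.asarray(weights, dtype=float)
    rot, _ = Rotation.align_vectors(obs - obs_mean, ref_c, weights=w)
    translation = obs_mean - rot.apply(ref_mean)
    # recompute the residual directly: the rssd reported by align_vectors
    # loses precision to cancellation for near-perfect fits
    resid = obs - (rot.apply(ref) + translation)
    wv = np.ones(n) if w is None else w
    rmsd = float(np.sqrt(np.sum(wv * np.sum(resid**2, axis=1)) / np.sum(wv)))
    return rot, translation, rmsd


def taitbryan_xyz(rotation: Rotation, gimbal_limit: float = 88.0) -> np.ndarray:
    """Decompose a rotation into XYZ-intrinsic Tait-Bryan angles (degrees).

    Returns ``[roll, pitch, yaw]``.  Emits :class:`GimbalWarning` when the
    pitch magnitude exceeds ``gimbal_limit``.
    """
    roll, pitch, yaw = rotation.as_euler("XYZ", degrees=True)
    if abs(pitch) >= gimbal_limit:
        warnings.warn(
            f"pitch {pitch:.2f} deg is near gimbal lock", GimbalWarning, stacklevel=2
        )
    return np.array([roll, pitch, yaw])


def rotation_from_taitbryan(roll: float, pitch: float, yaw: float) -> Rotation:
    """Inverse of :func:`taitbryan_xyz`."""
    return Rotation.from_euler("XYZ", [roll, pitch, yaw], degrees=True)


def _frame_positions(group: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        row.label: np.array([row.x_mm, row.y_mm, row.z_mm])
        for row in group.itertuples()
    }


def section_angles(
    markers: pd.DataFrame,
    layout: SectionLayout,
    geom: DeviceGeometry,
) -> pd.DataFrame:
    """Per-frame, per-section rigid transforms from labeled marker data.

    ``markers`` is long-format with columns ``time_s, label, x_mm, y_mm,
    z_mm``.  Sections with missing markers in a frame are skipped (local
    gap); frames never fail globally.  Returns one row per reconstructed
    section with its Tait-Bryan angles, center position and fit RMSD.
    """
    required = {"time_s", "label", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(markers.columns):
        raise ValueError(f"marker frame must have columns {sorted(required)}")
    rest = layout.rest_positions()
    anchor_back, anchor_front = layout.anchor_points()
    records = []
    for time_s, group in markers.groupby("time_s", sort=True):
        obs_by_label = _frame_positions(group)
        for sec_idx, labels in enumerate(layout.section_labels, start=1):
            if any(lab not in obs_by_label for lab in labels):
                continue
            ref = [rest[lab] for lab in labels]
            obs = [obs_by_label[lab] for lab in labels]
            if sec_idx == 1:
                ref.append(anchor_back)
                obs.append(anchor_back)
            elif sec_idx == N_SECTIONS:
                ref.append(anchor_front)
                obs.append(anchor_front)
            rot, trans, rmsd = kabsch_transform(np.array(ref), np.array(obs))
            roll, pitch, yaw = taitbryan_xyz(rot)
            # section center: fitted transform applied to the nominal center
            # (marker centroids are biased when the marker set is asymmetric)
            nominal_center = np.array(
                [0.5 * (layout.border_x[sec_idx - 1] + layout.border_x[sec_idx]), 0.0, 0.0]
            )
            center = rot.apply(nominal_center) + trans
            records.append(
                {
                    "time_s": time_s,
                    "section": sec_idx,
                    "roll_deg": roll,
                    "pitch_deg": pitch,
                    "yaw_deg": yaw,
                    "x_center_mm": center[0],
                    "y_center_mm": center[1],
                    "z_center_mm": center[2],
                    "rmsd_mm": rmsd,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "time_s",
            "section",
            "roll_deg",
            "pitch_deg",
            "yaw_deg",
            "x_center_mm",
            "y_center_mm",
            "z_center_mm",
            "rmsd_mm",
        ],
    )


def anchor_angles(sections: pd.DataFrame) -> AnchorAngles:
    """Normalized anchor-section angle series from reconstructed sections.

    Applies the model's sign normalization: the physical front-section pitch
    and yaw are flipped so that both pitches are positive for downward
    displacement and both yaws positive for displacement toward +Y.  Roll is
    left unflipped.
    """
    back = sections[sections["section"] == 1].sort_values("time_s")
    front = sections[sections["section"] == N_SECTIONS].sort_values("time_s")
    times = np.intersect1d(back["time_s"].to_numpy(), front["time_s"].to_numpy())
    back = back[back["time_s"].isin(times)]
    front = front[front["time_s"].isin(times)]
    return AnchorAngles(
        time=times,
        pitch_back=back["pitch_deg"].to_numpy(),
        pitch_front=-front["pitch_deg"].to_numpy(),
        yaw_back=back["yaw_deg"].to_numpy(),
        yaw_front=-front["yaw_deg"].to_numpy(),
        roll_back=back["roll_deg"].to_numpy(),
        roll_front=front["roll_deg"].to_numpy(),
    )


def rest_alignment(
    rest_markers: pd.DataFrame, layout: SectionLayout
) -> tuple[Rotation, np.ndarray]:
    """Rigid pre-transform aligning a recorded rest pose with the device axes.

    Fits a single rotation/translation mapping all rest-pose markers onto
    their nominal layout positions, so that the longitudinal tape axis is
    exactly the X-axis.  Apply with
    ``rot.apply(points) + trans`` before :func:`section_angles`.
    """
    rest = layout.rest_positions()
    obs_by_label = _frame_positions(rest_markers)
    labels = [lab for lab in rest if lab in obs_by_label]
    if len(labels) < 3:
        raise DegenerateGeometryError("rest pose needs at least 3 known markers")
    obs = np.array([obs_by_label[lab] for lab in labels])
    nominal = np.array([rest[lab] for lab in labels])
    rot, trans, _ = kabsch_transform(obs, nominal)
    return rot, trans
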