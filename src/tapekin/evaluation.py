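"""Reference extraction and accuracy statistics for model validation.

Per-trial RMSE, five-number percentile summaries (2/25/50/75/98) and
percentile profiles conditioned on a reference position channel.  Plots are
deliberately not produced here: the numbers are the contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import FrameMask

__all__ = [
    "PERCENTILES",
    "extract_reference",
    "rmse",
    "box_stats",
    "conditioned_profile",
    "summarize",
]

PERCENTILES = (2, 25, 50, 75, 98)


def extract_reference(
    sections: pd.DataFrame,
    foot_markers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-frame reference channels from reconstructed tape sections.

    Y and Z are taken from the section with the largest absolute vertical
    displacement; roll from the section with the largest absolute roll (the
    two argmaxes may differ).  Ties break toward the lower section index.
    The longitudinal reference X is the centroid of the foot markers when
    given, otherwise the x-center of the max-|Z| section.  Frames with no
    sections are dropped.
    """
    req = {"time_s", "section", "roll_deg", "y_center_mm", "z_center_mm", "x_center_mm"}
    if not req.issubset(sections.columns):
        raise ValueError(f"sections frame must have columns {sorted(req)}")
    rows = []
    for time_s, group in sections.groupby("time_s", sort=True):
        group = group.sort_values("section")
        if group.empty:
            continue
        zi = int(np.argmax(np.abs(group["z_center_mm"].to_numpy())))
        ri = int(np.argmax(np.abs(group["roll_deg"].to_numpy())))
        zrow = group.iloc[zi]
        rows.append(
            {
                "time_s": time_s,
                "x_mm": zrow["x_center_mm"],
                "y_mm": zrow["y_center_mm"],
                "z_mm": zrow["z_center_mm"],
                "roll_deg": group.iloc[ri]["roll_deg"],
            }
        )
    ref = pd.DataFrame(rows, columns=["time_s", "x_mm", "y_mm", "z_mm", "roll_deg"])
    if foot_markers is not None:
        cent = (
            foot_markers.groupby("time_s", sort=True)["x_mm"].mean().rename("x_foot")
        )
        ref = ref.merge(cent, on="time_s", how="left")
        has = ref["x_foot"].notna()
        ref.loc[has, "x_mm"] = ref.loc[has, "x_foot"]
        ref = ref.drop(columns="x_foot")
    return ref


def rmse(
    pred: np.ndarray,
    ref: np.ndarray,
    mask: FrameMask | None = None,
) -> float:
    """Root-mean-squared error over non-excluded frames.

    Residuals that are NaN (e.g. flagged non-numeric predictions) are
    omitted from the mean.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape:
        raise ValueError("pred/ref shape mismatch")
    keep = np.ones(p.shape, dtype=bool)
    if mask is not None:
        if len(mask) != len(p):
            raise ValueError("mask length mismatch")
        keep &= ~mask.excluded
    res = p[keep] - r[keep]
    res = res[np.isfinite(res)]
    if res.size == 0:
        raise ValueError("no usable frames for RMSE")
    return float(np.sqrt(np.mean(res**2)))


def box_stats(errors: np.ndarray) -> dict:
    """Five-number percentile summary with outliers beyond the whiskers.

    Percentiles use linear interpolation between order statistics.  The
    whiskers span the 2nd to 98th percentile; values outside are outliers.
    """
    e = np.asarray(errors, dtype=float)
    e = e[np.isfinite(e)]
    if e.size == 0:
        raise ValueError("no finite errors")
    p = np.percentile(e, PERCENTILES, method="linear")
    stats = {f"p{q}": float(v) for q, v in zip(PERCENTILES, p)}
    stats["n"] = int(e.size)
    stats["n_outliers"] = int(np.sum((e < stats["p2"]) | (e > stats["p98"])))
    return stats


def conditioned_profile(
    errors: np.ndarray,
    conditioner: np.ndarray,
    bins: int | np.ndarray = 10,
) -> pd.DataFrame:
    """Percentile curves of the error as a function of a reference channel.

    Returns one row per bin (``bin_center`` plus the five percentiles);
    empty bins are kept as NaN gaps.
    """
    e = np.asarray(errors, dtype=float)
    c = np.asarray(conditioner, dtype=float)
    if e.shape != c.shape:
        raise ValueError("errors/conditioner shape mismatch")
    ok = np.isfinite(e) & np.isfinite(c)
    edges = (
        np.histogram_bin_edges(c[ok], bins=bins)
        if np.isscalar(bins)
        else np.asarray(bins, dtype=float)
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(c, edges) - 1, 0, len(centers) - 1)
    rows = []
    for b, center in enumerate(centers):
        sel = ok & (idx == b) & (c >= edges[b]) & (c <= edges[b + 1])
        row = {"bin_center": float(center), "n": int(sel.sum())}
        if sel.any():
            p = np.percentile(e[sel], PERCENTILES, method="linear")
            row.update({f"p{q}": float(v) for q, v in zip(PERCENTILES, p)})
        else:
            row.update({f"p{q}": np.nan for q in PERCENTILES})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    estimates: pd.DataFrame,
    reference: pd.DataFrame,
    mask: FrameMask | None = None,
    outputs: dict[str, tuple[str, str]] | None = None,
) -> dict:
    """Per-output RMSE and box statistics for one trial.

    ``outputs`` maps an output name to ``(estimate column, reference
    column)``; the default covers the standard channels.
    """
    outputs = outputs or {
        "XZ": ("x_from_pitch_mm", "x_mm"),
        "XY": ("x_from_yaw_mm", "x_mm"),
        "Y": ("y_mm", "y_mm"),
        "Z": ("z_mm", "z_mm"),
        "ZR": ("z_corrected_mm", "z_mm"),
        "RM": ("roll_rm_deg", "roll_deg"),
        "RS": ("roll_rs_deg", "roll_deg"),
        "RWS": ("roll_rws_deg", "roll_deg"),
        "RA": ("roll_ra_deg", "roll_deg"),
    }
    if len(estimates) != len(reference):
        raise ValueError("estimates/reference length mismatch")
    summary: dict = {"n_frames": int(len(estimates)), "outputs": {}}
    if mask is not None:
        summary["n_excluded"] = int(np.sum(mask.excluded))
    for name, (pcol, rcol) in outputs.items():
        pred = estimates[pcol].to_numpy(dtype=float)
        ref = reference[rcol].to_numpy(dtype=float)
        err = pred - ref
        if mask is not None:
            err = err[~mask.excluded]
        finite = err[np.isfinite(err)]
        if finite.size == 0:
            summary["outputs"][name] = None
            continue
        entry = box_stats(finite)
        entry["rmse"] = float(np.sqrt(np.mean(finite**2)))
        summary["outputs"][name] = entry
    return summary
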