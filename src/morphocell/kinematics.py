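"""Scale-invariant migration kinematics and run/stop mode detection.

Uropod and centroid positions are smoothed with centered running means over
the significance timescale tau_sig, differenced, and divided by the time
step and the cube root of cell volume, giving velocities in s^-1 (cell
lengths per second) comparable across cells of different size.  The scalar
motion variable is the uropod speed along the uropod-to-centroid (UC) axis,
||Δuropod/Δt|| cos φ.  Long-window running means of this speed separate a
fast run mode (> 0.005 s^-1) from a near-stationary stop mode
(< 0.0025 s^-1), a bimodality that emerges only at windows around 150 s and
is quantified with Hartigan's dip test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .dip import dip_test
from .mesh_io import CellSequence


def running_mean(x: np.ndarray, window_frames: int) -> np.ndarray:
    """Centered running mean with shrinking windows at the edges."""
    if window_frames <= 1:
        return np.asarray(x, dtype=float).copy()
    s = pd.Series(np.asarray(x, dtype=float))
    return s.rolling(window=window_frames, center=True, min_periods=1).mean().to_numpy()


def _window_frames(window_s: float, dt: float) -> int:
    w = max(1, int(round(window_s / dt)))
    return w if w % 2 == 1 else w + 1


@dataclass
class KinematicsTrack:
    """Per-dataset kinematics: velocities, UC-axis speed, mode labels."""

    t: np.ndarray
    uropod_smooth: np.ndarray         # (n, 3) μm
    centroid_smooth: np.ndarray       # (n, 3) μm
    uropod_velocity: np.ndarray       # (n, 3) s^-1, scale-invariant
    centroid_velocity: np.ndarray     # (n, 3) s^-1
    speed_uc: np.ndarray              # (n,) signed s^-1
    speed_running: dict = field(default_factory=dict)   # window (s) -> (n,)
    mode: Optional[np.ndarray] = None
    cumulative: Optional[np.ndarray] = None
    undefined_axis: Optional[np.ndarray] = None

    def to_frame(self, dataset_id: str = "") -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t, "speed_uc": self.speed_uc})
        for w, s in self.speed_running.items():
            df[f"speed_mean_{int(w)}s"] = s
        if self.mode is not None:
            df["mode"] = self.mode
        if self.cumulative is not None:
            df["cumulative_speed"] = self.cumulative
        if dataset_id:
            df.insert(0, "dataset_id", dataset_id)
        return df


def velocities(
    seq: CellSequence,
    tau_sig: float,
    uropod: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed positions and scale-invariant velocities of uropod and centroid.

    Positions are smoothed with a centered running mean of width ``tau_sig``;
    velocities are successive differences divided by dt and by V^{1/3}
    (per-frame volume), in s^-1.  The last frame repeats the final
    difference so the series keeps one entry per frame.
    """
    n = len(seq)
    w = _window_frames(tau_sig, seq.dt)
    if w > n:
        raise ValueError(f"smoothing window of {w} frames exceeds series length {n}")
    uro = seq.uropods if uropod is None else np.asarray(uropod, dtype=float)
    if np.any(~np.isfinite(uro)):
        raise ValueError("uropod track contains gaps; interpolate first")
    cen = seq.centroids
    uro_s = np.column_stack([running_mean(uro[:, k], w) for k in range(3)])
    cen_s = np.column_stack([running_mean(cen[:, k], w) for k in range(3)])
    scale = np.cbrt(seq.volumes)[:, None] * seq.dt
    v_uro = np.empty_like(uro_s)
    v_cen = np.empty_like(cen_s)
    v_uro[:-1] = np.diff(uro_s, axis=0) / scale[:-1]
    v_cen[:-1] = np.diff(cen_s, axis=0) / scale[:-1]
    v_uro[-1] = v_uro[-2]
    v_cen[-1] = v_cen[-2]
    return uro_s, cen_s, v_uro, v_cen


def speed_uc(
    v_uropod: np.ndarray,
    uropod: np.ndarray,
    centroid: np.ndarray,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed uropod speed along the UC axis (positive = advancing forward).

    Projects the uropod velocity on the unit vector from uropod to centroid.
    Frames with uropod–centroid distance below ``tol`` get NaN and are
    flagged undefined.
    """
    axis = np.asarray(centroid, dtype=float) - np.asarray(uropod, dtype=float)
    norm = np.linalg.norm(axis, axis=1)
    undefined = norm < tol
    unit = np.zeros_like(axis)
    unit[~undefined] = axis[~undefined] / norm[~undefined, None]
    s = np.einsum("ij,ij->i", v_uropod, unit)
    s[undefined] = np.nan
    return s, undefined


def mode_classify(
    speed: np.ndarray,
    dt: float,
    config: Optional[RunConfig] = None,
    windows: Optional[Sequence[float]] = None,
) -> KinematicsTrack | dict:
    """Run/stop/transition labels from long-window running means of the speed.

    The running mean over ``config.mode_window`` (150 s default) is
    thresholded: run above ``run_threshold``, stop below ``stop_threshold``,
    transition in between.  Running means for every requested window and the
    cumulative speed (progress in cell lengths) are returned alongside.
    """
    cfg = config or RunConfig()
    wins = tuple(windows) if windows is not None else cfg.windows
    speed = np.asarray(speed, dtype=float)
    means = {w: running_mean(speed, _window_frames(w, dt)) for w in wins}
    wm = cfg.mode_window
    if wm not in means:
        means[wm] = running_mean(speed, _window_frames(wm, dt))
    base = means[wm]
    mode = np.where(base > cfg.run_threshold, "run", np.where(base < cfg.stop_threshold, "stop", "transition"))
    cumulative = np.nancumsum(speed) * dt
    return {
        "mode": mode,
        "running": means,
        "cumulative": cumulative,
    }


def bimodality_by_window(
    speeds_by_window: dict,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Hartigan dip test of the pooled speed distribution per running-mean window."""
    rows = []
    for w, vals in speeds_by_window.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        d, p = dip_test(v, n_boot=n_boot, seed=seed)
        rows.append({"window_s": w, "dip": d, "p_value": p, "n": len(v)})
    return pd.DataFrame(rows)


def track_kinematics(
    seq: CellSequence,
    tau_sig: float,
    uropod: Optional[np.ndarray] = None,
    config: Optional[RunConfig] = None,
) -> KinematicsTrack:
    """Full kinematics workup of one sequence."""
    cfg = config or RunConfig()
    uro_s, cen_s, v_uro, v_cen = velocities(seq, tau_sig, uropod=uropod)
    s, undef = speed_uc(v_uro, uro_s, cen_s)
    cls = mode_classify(s, seq.dt, cfg)
    return KinematicsTrack(
        t=seq.times,
        uropod_smooth=uro_s,
        centroid_smooth=cen_s,
        uropod_velocity=v_uro,
        centroid_velocity=v_cen,
        speed_uc=s,
        speed_running=cls["running"],
        mode=cls["mode"],
        cumulative=cls["cumulative"],
        undefined_axis=undef,
    )


def mode_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of decisively labeled frames (run/stop) matching ground truth."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    decisive = predicted != "transition"
    if decisive.sum() == 0:
        return 0.0
    return float(np.mean(predicted[decisive] == truth[decisive]))


def axis_alignment(
    seq: CellSequence,
    tau_sig: float,
    ellipsoid_axes: np.ndarray,
    uropod: Optional[np.ndarray] = None,
    config: Optional[RunConfig] = None,
    window_s: float = 100.0,
) -> pd.DataFrame:
    """Angles between long-timescale displacement, the UC axis and the ellipsoid axis.

    Positions are smoothed over ``window_s`` (100 s).  Only frames where the
    uropod speed exceeds the stop threshold (moving more than a quarter cell
    length in 100 s) and where uropod and centroid velocities agree to within
    half the uropod speed (aligned motion) are reported.  Returns an empty
    frame, not an error, when nothing passes.
    """
    cfg = config or RunConfig()
    n = len(seq)
    w = _window_frames(window_s, seq.dt)
    uro = seq.uropods if uropod is None else np.asarray(uropod, dtype=float)
    cen = seq.centroids
    uro_s = np.column_stack([running_mean(uro[:, k], w) for k in range(3)])
    cen_s = np.column_stack([running_mean(cen[:, k], w) for k in range(3)])
    scale = np.cbrt(seq.volumes)[:, None] * seq.dt
    v_uro = np.empty_like(uro_s)
    v_cen = np.empty_like(cen_s)
    v_uro[:-1] = np.diff(uro_s, axis=0) / scale[:-1]
    v_cen[:-1] = np.diff(cen_s, axis=0) / scale[:-1]
    v_uro[-1], v_cen[-1] = v_uro[-2], v_cen[-2]

    speed = np.linalg.norm(v_uro, axis=1)
    vel_gap = np.linalg.norm(v_uro - v_cen, axis=1)
    keep = (speed > cfg.stop_threshold) & (vel_gap <= 0.5 * speed)

    axes = np.asarray(ellipsoid_axes, dtype=float)
    uc = cen_s - uro_s
    rows = []
    for i in np.nonzero(keep)[0]:
        disp = v_uro[i]
        dn = np.linalg.norm(disp)
        ucn = np.linalg.norm(uc[i])
        if dn == 0 or ucn == 0:
            continue
        ang_uc = np.degrees(np.arccos(np.clip(np.dot(disp / dn, uc[i] / ucn), -1, 1)))
        row = {"frame": i, "t": seq.times[i], "angle_uc_deg": ang_uc}
        if np.all(np.isfinite(axes[i])):
            cosa = abs(np.dot(disp / dn, axes[i] / np.linalg.norm(axes[i])))
            row["angle_ellipsoid_deg"] = float(np.degrees(np.arccos(np.clip(cosa, -1, 1))))
        else:
            row["angle_ellipsoid_deg"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["frame", "t", "angle_uc_deg", "angle_ellipsoid_deg"])
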