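"""Uropod landmark handling: interpolation, uncertainty, significance timescale.

The uropod is a diffuse region, not a point, so the label carries a
positional uncertainty set by the local curvature of the cell rear: the
flatter (larger radius) the rear, the less constrained the label.  The
uncertainty is the chord of a 20 degree arc on the local rear radius, it is
propagated to the polarization descriptor D0 and on to PC coordinates, and
it sets the significance timescale tau_sig — the mean time the uropod needs
to move twice its uncertainty — used downstream as the velocity-smoothing
window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .config import RunConfig
from .mesh_io import CellFrame, CellSequence
from .spharm import polarization_d0

log = logging.getLogger(__name__)


@dataclass
class UropodTrack:
    """Per-dataset uropod track with uncertainty summaries."""

    positions: np.ndarray             # (n, 3), gaps filled
    interpolated: np.ndarray          # (n,) bool
    chord: float = np.nan             # characteristic positional uncertainty (μm)
    tau_sig: float = np.nan           # s
    sigma_d0: float = np.nan
    sigma_pc: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    flags: list = field(default_factory=list)

    @property
    def near_stationary(self) -> bool:
        return "near-stationary" in self.flags


def interpolate_labels(positions: np.ndarray, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate missing (NaN) uropod labels in time.

    Interior gaps are linear in time between the bracketing labels; leading/
    trailing gaps hold the nearest label constant.  Returns the filled (n, 3)
    array and a boolean flag per frame marking interpolated entries.
    """
    pos = np.asarray(positions, dtype=float).copy()
    t = np.asarray(times, dtype=float)
    labeled = np.isfinite(pos).all(axis=1)
    if labeled.sum() < 2:
        raise ValueError("need at least 2 labeled frames to interpolate")
    for ax in range(3):
        pos[~labeled, ax] = np.interp(t[~labeled], t[labeled], pos[labeled, ax])
    return pos, ~labeled


def mean_curvature_vertices(mesh: trimesh.Trimesh) -> np.ndarray:
    """Discrete per-vertex mean curvature via the cotangent Laplace–Beltrami.

    H_i = |K_i| / 2 with K_i the mean-curvature normal
    (1 / 2A_i) Σ_j (cot α_ij + cot β_ij)(x_i − x_j); the sign follows the
    outward vertex normal, so convex regions (a sphere) are positive with
    H = 1/R.
    """
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces)
    n = len(V)
    K = np.zeros((n, 3))
    area = np.zeros(n)
    for corner in range(3):
        a = F[:, corner]
        b = F[:, (corner + 1) % 3]
        c = F[:, (corner + 2) % 3]
        u = V[b] - V[a]
        w = V[c] - V[a]
        cross = np.cross(u, w)
        cn = np.linalg.norm(cross, axis=1)
        cot = np.einsum("ij,ij->i", u, w) / np.maximum(cn, 1e-300)
        # cot at corner a weights the opposite edge (b, c)
        np.add.at(K, b, 0.5 * cot[:, None] * (V[b] - V[c]))
        np.add.at(K, c, 0.5 * cot[:, None] * (V[c] - V[b]))
        np.add.at(area, a, cn / 6.0)  # barycentric third of face area
    # the half-cotangent accumulation above makes K the mean-curvature vector
    # H n directly (Meyer's 2H n halved)
    K = K / np.maximum(2.0 * area, 1e-300)[:, None]
    H = np.linalg.norm(K, axis=1)
    normals = np.asarray(mesh.vertex_normals)
    sign = np.sign(np.einsum("ij,ij->i", K, normals))
    return H * np.where(sign == 0, 1.0, sign)


def label_uncertainty(
    frame: CellFrame,
    config: Optional[RunConfig] = None,
    max_vertices: int = 2000,
) -> float:
    """Positional uncertainty (chord length, μm) of the frame's uropod label.

    The mean curvature averaged over the ``curvature_neighbors`` mesh vertices
    closest to the label gives an effective rear radius R = 1/H, and the
    uncertainty is the chord of a ``perturb_angle_deg`` arc at that radius:
    2 R sin(angle/2).  A non-convex rear (H <= 0) falls back to the
    uropod–centroid distance as the radius; ``chord_center='centroid'``
    forces that radius unconditionally.
    """
    cfg = config or RunConfig()
    if frame.uropod is None:
        raise ValueError("frame has no uropod label")
    half_angle = np.deg2rad(cfg.perturb_angle_deg) / 2.0
    dist_uc = float(np.linalg.norm(frame.uropod - frame.centroid))
    if cfg.chord_center == "centroid":
        return 2.0 * dist_uc * np.sin(half_angle)
    mesh = frame.mesh
    V = np.asarray(mesh.vertices)
    if len(V) > max_vertices:
        idx = np.linspace(0, len(V) - 1, max_vertices).astype(int)
    else:
        idx = np.arange(len(V))
    H_all = mean_curvature_vertices(mesh)
    tree = cKDTree(V[idx])
    _, nn = tree.query(frame.uropod, k=min(cfg.curvature_neighbors, len(idx)))
    H = float(np.mean(H_all[idx][np.atleast_1d(nn)]))
    if H <= 0:
        log.warning("non-convex rear (H=%.3g); falling back to uropod-centroid radius", H)
        R = dist_uc
    else:
        R = 1.0 / H
    return 2.0 * R * np.sin(half_angle)


def propagate_uncertainty(
    frame: CellFrame,
    chord: float,
    shape_space,
    config: Optional[RunConfig] = None,
) -> tuple[float, np.ndarray]:
    """Propagate the label chord to D0 and PC uncertainties for one frame.

    All mesh vertices within one chord of the label are alternative labels;
    the spread of their recomputed D0 values is sigma(D0), and each PC
    uncertainty is sigma(D0) times |cos| of the angle between the D0 axis and
    that PC's loading (the loading's D0 component, loadings being unit
    vectors).  sigma_PC <= sigma(D0) always.
    """
    cfg = config or RunConfig()
    V = np.asarray(frame.mesh.vertices)
    d = np.linalg.norm(V - frame.uropod, axis=1)
    cand = V[d <= chord]
    if len(cand) == 0:
        log.warning("no vertices within chord %.3g of label; sigma set to 0", chord)
        sigma_d0 = 0.0
    else:
        d0s = [polarization_d0(v, frame.centroid, frame.volume, cfg.d0_factor) for v in cand]
        sigma_d0 = float(np.std(d0s))
    k = shape_space.n_components
    cos = np.abs(shape_space.loadings[0, :k])
    return sigma_d0, sigma_d0 * cos


def tau_sig(
    positions: np.ndarray,
    times: np.ndarray,
    chord: float,
    cap: float = 100.0,
) -> tuple[float, bool]:
    """Mean first time for the uropod to move twice its uncertainty chord.

    For each start frame, the first later time at which the uropod's
    displacement from the start position exceeds 2*chord is recorded;
    tau_sig is the mean of those first-passage times, capped at ``cap``
    seconds.  Returns (tau_sig, near_stationary) where the flag marks
    datasets hitting the cap (excluded from quantitative speed analyses).
    """
    pos = np.asarray(positions, dtype=float)
    t = np.asarray(times, dtype=float)
    n = len(pos)
    if n < 2:
        raise ValueError("need at least 2 frames")
    target = 2.0 * chord
    passages = []
    for i in range(n - 1):
        disp = np.linalg.norm(pos[i + 1 :] - pos[i], axis=1)
        hit = np.nonzero(disp >= target)[0]
        if len(hit):
            passages.append(t[i + 1 + hit[0]] - t[i])
    if not passages:
        return cap, True
    tau = float(np.mean(passages))
    if tau >= cap:
        return cap, True
    return tau, False


def track_sequence(
    seq: CellSequence,
    shape_space=None,
    config: Optional[RunConfig] = None,
    every: int = 10,
) -> UropodTrack:
    """Full uncertainty workup of one dataset's uropod track.

    Labels are interpolated, the chord and (when a fitted shape space is
    supplied) the D0/PC uncertainties are evaluated every ``every`` frames and
    averaged into single characteristic values, and tau_sig is computed from
    the filled track.
    """
    cfg = config or RunConfig()
    pos, interp = interpolate_labels(seq.uropods, seq.times)
    chords = []
    sig_d0 = []
    sig_pc = []
    for i in range(0, len(seq), every):
        frame = seq.frames[i]
        f = CellFrame(mesh=frame.mesh, t=frame.t, uropod=pos[i])
        ch = label_uncertainty(f, cfg)
        chords.append(ch)
        if shape_space is not None:
            s0, spc = propagate_uncertainty(f, ch, shape_space, cfg)
            sig_d0.append(s0)
            sig_pc.append(spc)
    chord = float(np.mean(chords))
    tau, stationary = tau_sig(pos, seq.times, chord, cap=cfg.tau_sig_cap)
    track = UropodTrack(
        positions=pos,
        interpolated=interp,
        chord=chord,
        tau_sig=tau,
        sigma_d0=float(np.mean(sig_d0)) if sig_d0 else np.nan,
        sigma_pc=np.mean(sig_pc, axis=0) if sig_pc else np.full(3, np.nan),
    )
    if stationary:
        track.flags.append("near-stationary")
    return track


def propose_rear(seq: CellSequence) -> np.ndarray:
    """Heuristic rear proposal for unlabeled sequences (unscored helper).

    Works only when vertex correspondence persists across frames (as in the
    synthetic generator): picks the vertex with the smallest mean
    frame-to-frame motion after removing the centroid drift — the smooth,
    stationary rear — and returns its position per frame.
    """
    counts = {len(f.mesh.vertices) for f in seq.frames}
    if len(counts) != 1:
        raise ValueError("rear proposal needs persistent vertex correspondence")
    P = np.stack([np.asarray(f.mesh.vertices) - f.centroid for f in seq.frames])
    motion = np.linalg.norm(np.diff(P, axis=0), axis=2).mean(axis=0)
    k = int(np.argmin(motion))
    return np.stack([np.asarray(f.mesh.vertices)[k] for f in seq.frames])
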