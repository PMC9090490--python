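"""Spherical-harmonic (SPHARM) shape descriptors for genus-0 cell surfaces.

The surface is mapped bijectively to the unit sphere, the three Cartesian
coordinate functions {x(θ,φ), y(θ,φ), z(θ,φ)} are expanded in orthonormal
complex spherical harmonics Y_l^m (Condon–Shortley phase, m ≥ 0 stored; the
negative orders of a real-valued function are implied by conjugate
symmetry), and the morphology is summarized by the invariant descriptor

    D_l = sqrt( Σ_{i∈{x,y,z}} [ |c_{l,i}^0|² + 2 Σ_{m>0} |c_{l,i}^m|² ] ),  l ≥ 1,

with coefficients divided by V^{1/3} for scale invariance and the l = 0
(centroid) terms omitted for translation invariance.  Rotations of the cell
mix coefficients only within a degree l and across the three coordinates,
leaving each D_l exactly unchanged.  The extra polarization descriptor

    D_0 = (√3 / 2) · ‖uropod − centroid‖ / V^{1/3}

restores the front–rear orientation information a purely global rotational
invariant discards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse
import trimesh
from scipy.special import sph_harm_y

from .config import RunConfig
from .mesh_io import CellSequence, mesh_volume_centroid

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# spherical parameterization
# ---------------------------------------------------------------------------

@dataclass
class SphericalMap:
    """Bijective map of mesh vertices onto the unit sphere."""

    unit: np.ndarray           # (n, 3) unit vectors
    n_flipped: int = 0
    area_distortion: float = 1.0   # max/min per-face (mesh area)/(sphere area) ratio
    iterations: int = 0

    @property
    def theta(self) -> np.ndarray:
        return np.arccos(np.clip(self.unit[:, 2], -1.0, 1.0))

    @property
    def phi(self) -> np.ndarray:
        return np.mod(np.arctan2(self.unit[:, 1], self.unit[:, 0]), 2 * np.pi)


def _spherical_face_orientation(unit: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Signed volume of the origin-tetrahedron per spherical triangle.

    Positive for outward-consistent (non-inverted) spherical triangles.
    """
    a, b, c = unit[faces[:, 0]], unit[faces[:, 1]], unit[faces[:, 2]]
    return np.einsum("ij,ij->i", a, np.cross(b, c))


def _spherical_face_areas(unit: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Solid angle of each spherical triangle (Van Oosterom–Strackee)."""
    a, b, c = unit[faces[:, 0]], unit[faces[:, 1]], unit[faces[:, 2]]
    num = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)))
    den = (
        1.0
        + np.einsum("ij,ij->i", a, b)
        + np.einsum("ij,ij->i", b, c)
        + np.einsum("ij,ij->i", a, c)
    )
    return 2.0 * np.arctan2(num, den)


def _vertex_adjacency(n: int, faces: np.ndarray) -> scipy.sparse.csr_matrix:
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2], faces[:, 1], faces[:, 2], faces[:, 0]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0], faces[:, 0], faces[:, 1], faces[:, 2]])
    data = np.ones(len(i))
    adj = scipy.sparse.csr_matrix((data, (i, j)), shape=(n, n))
    adj.data[:] = 1.0
    return adj


def _l1_linear_map(X: np.ndarray, unit: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """3x3 linear map M of the degree-1 surface component: f(n) ≈ M n.

    Area-weighted least squares of the centered vertex positions against the
    map directions (the degree-1 harmonics span exactly the linear functions
    of n, so this is the l = 1 fit restricted to its own subspace).
    """
    w = vertex_sphere_areas(unit, faces)
    sw = np.sqrt(w)[:, None]
    M_t, *_ = np.linalg.lstsq(unit * sw, X * sw, rcond=None)
    return M_t.T


def parameterize_surface(
    mesh: trimesh.Trimesh,
    max_iter: int = 200,
    tol: float = 1e-6,
    step: float = 0.25,
    target_spread: float = 2.5,
) -> SphericalMap:
    """Map a genus-0 mesh to the unit sphere with controlled area distortion.

    The initial map is the radial (Gauss) projection taken in
    anisotropy-whitened coordinates: vertices are first transformed by the
    inverse square root of the area-weighted vertex covariance, which sends
    the best-fit ellipsoid to a sphere, then projected radially.  For an
    exact ellipsoid this reproduces the parameterization in which the
    surface is purely degree-1, so low-order spectral content is preserved
    (a fully area-equalized map of a 2:1 ellipsoid loses ~8% of its
    elongation to higher degrees).  Any inverted spherical triangles are
    removed by Laplacian (Tutte-style) smoothing; vertices are then relaxed
    toward equalized area distortion, but only until the per-face
    (mesh area)/(sphere area) spread max/min falls to ``target_spread`` —
    enough to keep strongly protrusive surfaces well conditioned without
    eroding the ellipsoid component.  The whole construction is equivariant
    under rigid rotation, uniform scaling and vertex reindexing.
    """
    if mesh.euler_number != 2 or not mesh.is_watertight:
        raise ValueError("spherical parameterization requires a closed genus-0 mesh")
    faces = np.asarray(mesh.faces)
    _, centroid = mesh_volume_centroid(mesh)
    vec = np.asarray(mesh.vertices, dtype=float) - centroid

    # anisotropy whitening, made self-consistent with the degree-1 fit:
    # project with normalization A, fit the l=1 linear map M of the surface,
    # set A <- M and repeat.  The fixed point sends an exact ellipsoid to the
    # parameterization in which it is purely degree-1.
    va = np.zeros(len(vec))
    np.add.at(va, faces.ravel(), np.repeat(np.asarray(mesh.area_faces) / 3.0, 3))
    va = va / va.sum()
    mu = va @ vec
    X = vec - mu
    C = (X * va[:, None]).T @ X
    evals, evecs = np.linalg.eigh(C)
    if np.min(evals) <= 0:
        raise ValueError("degenerate vertex covariance; cannot whiten")
    A = evecs @ np.diag(np.sqrt(evals)) @ evecs.T

    unit = None
    for _ in range(4):
        white = X @ np.linalg.inv(A).T
        norms = np.linalg.norm(white, axis=1)
        if np.any(norms == 0):
            raise ValueError("vertex coincides with centroid; cannot build radial map")
        unit = white / norms[:, None]
        if np.any(_spherical_face_orientation(unit, faces) <= 0):
            break  # non-star-shaped under this whitening: stop refining
        M = _l1_linear_map(X, unit, faces)
        if np.linalg.cond(M) > 1e6:
            break
        A = M

    adj = _vertex_adjacency(len(unit), faces)
    deg = np.asarray(adj.sum(axis=1)).ravel()

    # remove inversions with uniform Laplacian smoothing on the sphere
    for _ in range(200):
        orient = _spherical_face_orientation(unit, faces)
        if np.all(orient > 0):
            break
        unit = 0.5 * unit + 0.5 * (adj @ unit) / deg[:, None]
        unit /= np.linalg.norm(unit, axis=1)[:, None]
    else:
        n_bad = int(np.sum(_spherical_face_orientation(unit, faces) <= 0))
        raise ValueError(f"failed to remove {n_bad} inverted spherical triangles")

    mesh_fa = np.asarray(mesh.area_faces, dtype=float)
    mesh_fa = mesh_fa / mesh_fa.sum()
    n_v = len(unit)
    f_rows = np.repeat(np.arange(len(faces)), 3)
    f_cols = faces.ravel()
    incidence = scipy.sparse.csr_matrix(
        (np.ones(len(f_rows)), (f_cols, f_rows)), shape=(n_v, len(faces))
    )
    n_incident = np.maximum(incidence @ np.ones(len(faces)), 1)

    def ratio_and_energy(u):
        sph = _spherical_face_areas(u, faces)
        sph = sph / sph.sum()
        ratio = mesh_fa / np.maximum(sph, 1e-15)
        # mesh-area-weighted RMS log distortion: smooth, scale-free objective
        energy = float(np.sqrt(np.sum(mesh_fa * np.log(ratio) ** 2)))
        return ratio, energy

    ratio, energy = ratio_and_energy(unit)
    it = 0
    for it in range(1, max_iter + 1):
        if float(np.max(ratio) / np.min(ratio)) <= target_spread:
            break
        # per-vertex spherical-area surplus: >1 where the sphere over-represents
        # the mesh; vertices drift toward surplus regions, consuming the excess
        surplus = (incidence @ (1.0 / ratio)) / n_incident
        target = (adj @ (unit * surplus[:, None])) / np.maximum(adj @ surplus, 1e-12)[:, None]
        prop = unit + step * (target - unit)
        prop /= np.linalg.norm(prop, axis=1)[:, None]
        if np.any(_spherical_face_orientation(prop, faces) <= 0):
            step *= 0.5
            if step < 1e-4:
                break
            continue
        new_ratio, new_energy = ratio_and_energy(prop)
        if new_energy >= energy:
            step *= 0.5
            if step < 1e-4:
                break
            continue
        rel_change = (energy - new_energy) / max(energy, 1e-15)
        unit, ratio, energy = prop, new_ratio, new_energy
        step = min(step * 1.3, 0.9)  # monotone descent allows regrowing the step
        if rel_change < tol:
            break

    spread = float(np.max(ratio) / np.min(ratio))
    return SphericalMap(unit=unit, n_flipped=0, area_distortion=spread, iterations=it)


# ---------------------------------------------------------------------------
# harmonic fitting
# ---------------------------------------------------------------------------

def harmonic_index(l_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Degree/order arrays for the m ≥ 0 coefficient layout."""
    ls, ms = [], []
    for l in range(l_max + 1):
        for m in range(l + 1):
            ls.append(l)
            ms.append(m)
    return np.array(ls), np.array(ms)


def complex_basis(theta: np.ndarray, phi: np.ndarray, l_max: int) -> np.ndarray:
    """(n, n_coef) matrix of orthonormal Y_l^m(θ, φ), m ≥ 0 layout."""
    ls, ms = harmonic_index(l_max)
    out = np.empty((len(theta), len(ls)), dtype=complex)
    for k, (l, m) in enumerate(zip(ls, ms)):
        out[:, k] = sph_harm_y(l, m, theta, phi)
    return out


def _real_design(theta: np.ndarray, phi: np.ndarray, l_max: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Real design matrix for fitting real functions with complex m ≥ 0 coefficients.

    f(θ,φ) = Σ_l [ c_{l0} Y_l^0 + Σ_{m>0} 2 Re(c_{lm} Y_l^m) ] with c_{l0} real.
    Columns: Re part per (l,0), then per (l,m>0): 2·Re(Y), −2·Im(Y) multiplying
    Re(c) and Im(c) respectively.
    """
    ls, ms = harmonic_index(l_max)
    Y = complex_basis(theta, phi, l_max)
    cols = []
    col_map = []  # (coef_index, part) with part 0=real, 1=imag
    for k, (l, m) in enumerate(zip(ls, ms)):
        if m == 0:
            cols.append(Y[:, k].real)
            col_map.append((k, 0))
        else:
            cols.append(2.0 * Y[:, k].real)
            col_map.append((k, 0))
            cols.append(-2.0 * Y[:, k].imag)
            col_map.append((k, 1))
    return np.column_stack(cols), np.array(col_map), ls


@dataclass
class SpharmCoeffs:
    """Complex SPHARM coefficients c_{l,i}^m, m ≥ 0, for the three coordinates."""

    c: np.ndarray              # (3, n_coef) complex; rows x, y, z
    ls: np.ndarray             # degree per coefficient column
    ms: np.ndarray             # order per coefficient column
    l_max: int
    volume: float
    scale_normalized: bool = False
    rms_residual: float = 0.0

    def normalized(self) -> "SpharmCoeffs":
        """Coefficients divided by V^{1/3} (scale invariance)."""
        if self.scale_normalized:
            return self
        return SpharmCoeffs(
            c=self.c / self.volume ** (1.0 / 3.0),
            ls=self.ls,
            ms=self.ms,
            l_max=self.l_max,
            volume=self.volume,
            scale_normalized=True,
            rms_residual=self.rms_residual,
        )

    def power_per_degree(self, double_count_m: bool = True) -> np.ndarray:
        """Rotational-invariant power Σ_i Σ_m |c|² per degree l (l = 0 … l_max)."""
        mult = np.where(self.ms > 0, 2.0, 1.0) if double_count_m else np.ones_like(self.ms, dtype=float)
        p = (np.abs(self.c) ** 2 * mult[None, :]).sum(axis=0)
        out = np.zeros(self.l_max + 1)
        np.add.at(out, self.ls, p)
        return out

    @property
    def centroid(self) -> np.ndarray:
        """Centroid encoded by the l = 0 coefficients (Y_0^0 = 1/sqrt(4π))."""
        k0 = self.ls == 0
        return (self.c[:, k0].real.ravel()) / np.sqrt(4 * np.pi)


def vertex_sphere_areas(unit: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex barycentric share of spherical triangle areas (quadrature weights)."""
    fa = _spherical_face_areas(unit, faces)
    w = np.zeros(len(unit))
    np.add.at(w, faces.ravel(), np.repeat(fa / 3.0, 3))
    return w


def fit_coefficients(
    mesh: trimesh.Trimesh,
    smap: SphericalMap,
    l_max: int = 15,
    weighted: bool = True,
) -> SpharmCoeffs:
    """Weighted least-squares fit of the coordinate functions in Y_l^m, m ≥ 0.

    Per-vertex weights are the spherical barycentric areas of the map, so the
    fit approximates the continuous L² projection instead of biasing toward
    densely mapped regions.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    verts = np.asarray(mesh.vertices, dtype=float)
    n_coef_real = (l_max + 1) ** 2
    if len(verts) < n_coef_real:
        raise ValueError(f"{len(verts)} vertices cannot constrain {n_coef_real} coefficients")
    A, col_map, ls = _real_design(smap.theta, smap.phi, l_max)
    b = verts.copy()
    if weighted:
        w = vertex_sphere_areas(smap.unit, np.asarray(mesh.faces))
        sw = np.sqrt(w)[:, None]
        beta, *_ = np.linalg.lstsq(A * sw, b * sw, rcond=None)
    else:
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = A @ beta - b
    rms = float(np.sqrt(np.mean(resid**2)))

    ls_full, ms_full = harmonic_index(l_max)
    c = np.zeros((3, len(ls_full)), dtype=complex)
    for col, (k, part) in enumerate(col_map):
        if part == 0:
            c[:, k] += beta[col]
        else:
            c[:, k] += 1j * beta[col]
    vol, _ = mesh_volume_centroid(mesh)
    return SpharmCoeffs(c=c, ls=ls_full, ms=ms_full, l_max=l_max, volume=vol, rms_residual=rms)


def reconstruct(
    coeffs: SpharmCoeffs,
    l_trunc: Optional[int] = None,
    sphere_subdivisions: int = 3,
    smap: Optional[SphericalMap] = None,
    faces: Optional[np.ndarray] = None,
) -> trimesh.Trimesh:
    """Evaluate the truncated expansion on a spherical sampling.

    ``l_trunc = 1`` yields the ellipsoid component of the shape; increasing
    ``l_trunc`` adds detail.  By default a regular icosphere sampling is
    used; passing the original ``smap`` (with the source mesh ``faces``)
    evaluates at the data parameterization instead, giving vertex-wise
    correspondence with the input mesh.
    """
    l_trunc = coeffs.l_max if l_trunc is None else l_trunc
    if not (1 <= l_trunc <= coeffs.l_max):
        raise ValueError("l_trunc must lie in [1, l_max]")
    if smap is not None:
        if faces is None:
            raise ValueError("faces required when evaluating at a data parameterization")
        theta, phi, out_faces = smap.theta, smap.phi, np.asarray(faces)
    else:
        sphere = trimesh.creation.icosphere(subdivisions=sphere_subdivisions, radius=1.0)
        u = np.asarray(sphere.vertices)
        theta = np.arccos(np.clip(u[:, 2], -1, 1))
        phi = np.mod(np.arctan2(u[:, 1], u[:, 0]), 2 * np.pi)
        out_faces = np.asarray(sphere.faces)
    Y = complex_basis(theta, phi, coeffs.l_max)
    keep = coeffs.ls <= l_trunc
    mult = np.where(coeffs.ms > 0, 2.0, 1.0)
    # real part of Σ c Y with m>0 doubled reproduces the real function
    vals = np.real(Y[:, keep] @ (coeffs.c[:, keep] * mult[None, keep]).T)
    return trimesh.Trimesh(vertices=vals, faces=out_faces, process=False)


# ---------------------------------------------------------------------------
# invariant descriptor
# ---------------------------------------------------------------------------

@dataclass
class ShapeDescriptor:
    """16-element invariant shape vector {D_0 … D_15}."""

    D: np.ndarray
    volume: float
    uropod: Optional[np.ndarray] = None
    centroid: Optional[np.ndarray] = None

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        if np.any(self.D < 0) or not np.all(np.isfinite(self.D)):
            raise ValueError("descriptor entries must be finite and non-negative")


def polarization_d0(
    uropod: np.ndarray,
    centroid: np.ndarray,
    volume: float,
    d0_factor: float = np.sqrt(3.0) / 2.0,
) -> float:
    """D_0 = d0_factor · ‖uropod − centroid‖ / V^{1/3}."""
    return float(d0_factor * np.linalg.norm(np.asarray(uropod) - np.asarray(centroid)) / volume ** (1.0 / 3.0))


def invariant_descriptor(
    coeffs: SpharmCoeffs,
    uropod: np.ndarray,
    centroid: np.ndarray,
    config: Optional[RunConfig] = None,
) -> ShapeDescriptor:
    """Rotation/scale/translation-invariant descriptor from fitted coefficients.

    D_l (l ≥ 1) is the square root of the per-degree coefficient power with
    m > 0 terms double-counted for the implied negative orders; l = 0 terms
    are dropped (translation invariance); coefficients are scale-normalized
    by V^{1/3}.  D_0 is the scaled uropod–centroid distance.
    """
    cfg = config or RunConfig()
    if uropod is None:
        raise ValueError("uropod landmark required for the polarization descriptor D0")
    nc = coeffs.normalized()
    power = nc.power_per_degree(double_count_m=cfg.double_count_m)
    D = np.zeros(nc.l_max + 1)
    D[1:] = np.sqrt(power[1:])
    D[0] = polarization_d0(uropod, centroid, coeffs.volume, cfg.d0_factor)
    return ShapeDescriptor(D=D, volume=coeffs.volume, uropod=np.asarray(uropod), centroid=np.asarray(centroid))


def ellipsoid_axis(
    coeffs: SpharmCoeffs,
    uropod: Optional[np.ndarray] = None,
    centroid: Optional[np.ndarray] = None,
    degenerate_tol: float = 0.02,
) -> tuple[Optional[np.ndarray], bool]:
    """Major axis of the shape's ellipsoid (l = 1) component.

    The l = 1 part of the expansion is a linear map of the unit direction,
    n ↦ M n; the major axis is the leading right-singular vector of M
    (equivalently the top eigenvector of MᵀM built from the l = 1
    coefficients).  Returns ``(axis, degenerate)``; near-spherical shapes
    (top two singular values within ``degenerate_tol`` relative) are flagged
    degenerate with ``axis=None``.  When a uropod is given the sign points
    toward the cell front (away from the uropod).
    """
    k0 = np.sqrt(3.0 / (4.0 * np.pi))
    k1 = np.sqrt(3.0 / (8.0 * np.pi))
    i10 = np.where((coeffs.ls == 1) & (coeffs.ms == 0))[0][0]
    i11 = np.where((coeffs.ls == 1) & (coeffs.ms == 1))[0][0]
    M = np.empty((3, 3))
    # Y_1^0 = k0 z ; 2 Re(c Y_1^1) = -2 k1 (Re c · x - Im c · y)
    M[:, 0] = -2.0 * k1 * coeffs.c[:, i11].real
    M[:, 1] = 2.0 * k1 * coeffs.c[:, i11].imag
    M[:, 2] = k0 * coeffs.c[:, i10].real
    _, s, vt = np.linalg.svd(M)
    if s[0] <= 0 or (s[0] - s[1]) / s[0] < degenerate_tol:
        return None, True
    axis = vt[0]
    # map the sphere-space axis to object space direction of maximal extent
    axis_obj = M @ axis
    axis_obj /= np.linalg.norm(axis_obj)
    if uropod is not None and centroid is not None:
        front = np.asarray(centroid) - np.asarray(uropod)
        if np.dot(axis_obj, front) < 0:
            axis_obj = -axis_obj
    return axis_obj, False


# ---------------------------------------------------------------------------
# per-sequence descriptor table
# ---------------------------------------------------------------------------

def descriptor_series(
    seq: CellSequence,
    config: Optional[RunConfig] = None,
    interpolate: bool = True,
):
    """Descriptor table for a sequence: one row per frame, columns D0…D15 etc.

    Uropod labels are linearly interpolated over missing frames first (the
    standard alternating-frame labelling).  Returns a pandas DataFrame with
    columns dataset_id, frame, t, D0..D{l_max}, V, uropod/centroid xyz.
    """
    import pandas as pd

    from .uropod import interpolate_labels

    cfg = config or RunConfig()
    uro = seq.uropods
    if interpolate and np.any(~np.isfinite(uro[:, 0])):
        uro, _ = interpolate_labels(uro, seq.times)
    rows = []
    for i, frame in enumerate(seq.frames):
        smap = parameterize_surface(frame.mesh)
        coeffs = fit_coefficients(frame.mesh, smap, l_max=cfg.l_max)
        desc = invariant_descriptor(coeffs, uro[i], frame.centroid, cfg)
        row = {"dataset_id": seq.dataset_id, "frame": i, "t": frame.t, "V": frame.volume}
        for l in range(cfg.l_max + 1):
            row[f"D{l}"] = desc.D[l]
        for ax, name in enumerate("xyz"):
            row[f"uropod_{name}"] = uro[i, ax]
            row[f"centroid_{name}"] = frame.centroid[ax]
        rows.append(row)
    return pd.DataFrame(rows)


def descriptor_columns(l_max: int = 15) -> list[str]:
    return [f"D{l}" for l in range(l_max + 1)]
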