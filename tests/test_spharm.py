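import numpy as np
import pytest
import trimesh

from morphocell.config import RunConfig
from morphocell.mesh_io import mesh_volume_centroid
from morphocell.spharm import (
    ellipsoid_axis,
    fit_coefficients,
    invariant_descriptor,
    parameterize_surface,
    polarization_d0,
    reconstruct,
    vertex_sphere_areas,
)
from morphocell.synthetic import SynthCellParams, make_cell_sequence

from conftest import random_rotation


def full_descriptor(mesh, uropod, centroid, l_max=15):
    smap = parameterize_surface(mesh)
    coeffs = fit_coefficients(mesh, smap, l_max=l_max)
    return invariant_descriptor(coeffs, uropod, centroid), coeffs, smap


class TestParameterization:
    def test_sphere_map_is_radial(self, unit_sphere):
        smap = parameterize_surface(unit_sphere)
        radial = np.asarray(unit_sphere.vertices)
        radial = radial / np.linalg.norm(radial, axis=1)[:, None]
        cosang = np.einsum("ij,ij->i", smap.unit, radial)
        assert np.degrees(np.arccos(np.clip(cosang.min(), -1, 1))) < 5.0

    def test_ellipsoid_no_inversions_low_distortion(self, ellipsoid211):
        smap = parameterize_surface(ellipsoid211)
        assert smap.n_flipped == 0
        assert smap.area_distortion < 10.0

    def test_reindexing_gives_same_map(self, ellipsoid211):
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(ellipsoid211.vertices))
        inv = np.argsort(perm)
        m = trimesh.Trimesh(vertices=np.asarray(ellipsoid211.vertices)[perm],
                            faces=inv[np.asarray(ellipsoid211.faces)], process=False)
        a = parameterize_surface(ellipsoid211).unit
        b = parameterize_surface(m).unit
        assert np.allclose(a, b[inv], atol=1e-8)

    def test_torus_rejected(self):
        with pytest.raises(ValueError):
            parameterize_surface(trimesh.creation.torus(major_radius=3.0, minor_radius=1.0))


class TestCoefficients:
    def test_sphere_power_concentrates_at_l1(self, unit_sphere):
        """Quadrature oracle: a centered sphere's coordinate functions are pure
        degree-1; total centered power equals the surface integral of |x|²."""
        smap = parameterize_surface(unit_sphere)
        coeffs = fit_coefficients(unit_sphere, smap, l_max=15)
        p = coeffs.power_per_degree()
        assert p[2:].sum() / p[1:].sum() < 1e-3
        w = vertex_sphere_areas(smap.unit, np.asarray(unit_sphere.faces))
        oracle_power = float(np.sum(w * np.linalg.norm(unit_sphere.vertices, axis=1) ** 2))
        assert p[1] == pytest.approx(oracle_power, rel=0.01)

    def test_translation_moves_only_l0(self, ellipsoid211):
        smap = parameterize_surface(ellipsoid211)
        c0 = fit_coefficients(ellipsoid211, smap, l_max=8)
        shifted = trimesh.Trimesh(vertices=np.asarray(ellipsoid211.vertices) + [10, 0, 0],
                                  faces=ellipsoid211.faces, process=False)
        c1 = fit_coefficients(shifted, parameterize_surface(shifted), l_max=8)
        dif = np.abs(c1.c - c0.c)
        l0_cols = c0.ls == 0
        assert dif[0, l0_cols].max() > 1.0          # x-centroid moved
        assert dif[:, ~l0_cols].max() < 1e-6        # everything else unchanged
        assert np.allclose(c1.centroid - c0.centroid, [10, 0, 0], atol=1e-6)

    def test_reconstruction_error_decreases_with_lmax(self, small_cell_seq):
        mesh = small_cell_seq.frames[0].mesh
        smap = parameterize_surface(mesh)
        rms = [fit_coefficients(mesh, smap, l_max=l).rms_residual for l in (8, 15)]
        assert rms[1] <= rms[0]

    def test_too_few_vertices_raises(self):
        m = trimesh.creation.icosphere(subdivisions=1)  # 42 vertices
        with pytest.raises(ValueError):
            fit_coefficients(m, parameterize_surface(m), l_max=15)


class TestReconstruct:
    def test_ellipsoid_l1_semi_axes(self, ellipsoid211):
        smap = parameterize_surface(ellipsoid211)
        coeffs = fit_coefficients(ellipsoid211, smap, l_max=15)
        rec = reconstruct(coeffs, l_trunc=1)
        pts = np.asarray(rec.vertices) - np.asarray(rec.vertices).mean(0)
        evals = np.linalg.eigvalsh(pts.T @ pts / len(pts))
        semi = np.sqrt(3 * evals)  # uniform sphere sampling: Cov = M Mᵀ/3
        assert np.sort(semi) == pytest.approx([1.0, 1.0, 2.0], rel=0.02)

    def test_sphere_full_reconstruction_near_identity(self, unit_sphere):
        smap = parameterize_surface(unit_sphere)
        coeffs = fit_coefficients(unit_sphere, smap, l_max=15)
        rec = reconstruct(coeffs, l_trunc=15, smap=smap, faces=unit_sphere.faces)
        err = np.linalg.norm(np.asarray(rec.vertices) - np.asarray(unit_sphere.vertices), axis=1)
        assert err.max() < 0.01  # < 1% of radius

    def test_truncation_error_non_increasing(self):
        seq = make_cell_sequence(
            SynthCellParams(seed=21, vertex_noise_sd=0.0, landmark_jitter_sd=0.0,
                            mesh_subdivisions=4), 3, 5.0)
        mesh = seq.frames[1].mesh
        smap = parameterize_surface(mesh)
        coeffs = fit_coefficients(mesh, smap, l_max=15)
        errs = []
        for lt in (1, 3, 6, 10, 15):
            rec = reconstruct(coeffs, l_trunc=lt, smap=smap, faces=mesh.faces)
            errs.append(np.sqrt(np.mean((np.asarray(rec.vertices) - np.asarray(mesh.vertices)) ** 2)))
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_invalid_l_trunc(self, unit_sphere):
        smap = parameterize_surface(unit_sphere)
        coeffs = fit_coefficients(unit_sphere, smap, l_max=4)
        with pytest.raises(ValueError):
            reconstruct(coeffs, l_trunc=0)


class TestDescriptor:
    def test_sphere_oracle(self, unit_sphere, cfg):
        """D0 for a rear-point label on a unit sphere, with the volume from
        quadrature (divergence theorem) rather than the descriptor path."""
        desc, coeffs, smap = full_descriptor(unit_sphere, np.array([0, 0, -1.0]), np.zeros(3))
        # oracle volume: V = (1/3)∮ x·n dA over mesh faces
        tri = np.asarray(unit_sphere.vertices)[np.asarray(unit_sphere.faces)]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        v_oracle = float(np.sum(np.einsum("ij,ij->i", tri.mean(axis=1), cross)) / 6.0)
        d0_oracle = np.sqrt(3) / 2 * 1.0 / v_oracle ** (1 / 3)
        assert desc.D[0] == pytest.approx(d0_oracle, rel=0.01)
        assert desc.D[2:].max() < 1e-3 * desc.D.max()

    def test_rotation_scale_translation_invariance(self, small_cell_seq):
        frame = small_cell_seq.frames[2]
        d0 = full_descriptor(frame.mesh, frame.uropod, frame.centroid)[0].D
        scale_max = d0.max()
        for k in range(10):
            R = random_rotation(k)
            s = [0.3, 1.0, 3.0][k % 3]
            shift = np.array([k, -2.0 * k, 5.0])
            verts = s * (np.asarray(frame.mesh.vertices) @ R.T) + shift
            m = trimesh.Trimesh(vertices=verts, faces=frame.mesh.faces, process=False)
            d1 = full_descriptor(m, s * (R @ frame.uropod) + shift, s * (R @ frame.centroid) + shift)[0].D
            assert np.max(np.abs(d1 - d0)) < 1e-6 * scale_max

    def test_polarization_term_alone_tracks_uropod_distance(self, ellipsoid211):
        """Two frames with identical geometry but different labels differ only
        in D0, by the predicted amount."""
        vol, cen = mesh_volume_centroid(ellipsoid211)
        dA, _, _ = full_descriptor(ellipsoid211, np.array([-2.0, 0, 0]), cen)
        dB, _, _ = full_descriptor(ellipsoid211, np.array([-1.4, 0, 0]), cen)
        delta = np.abs(dA.D - dB.D)
        assert np.argmax(delta) == 0
        assert delta[0] == pytest.approx(np.sqrt(3) / 2 * 0.6 / vol ** (1 / 3), rel=1e-6)
        assert delta[1:].max() < 1e-12

    def test_missing_uropod_raises(self, unit_sphere):
        smap = parameterize_surface(unit_sphere)
        coeffs = fit_coefficients(unit_sphere, smap, l_max=4)
        with pytest.raises(ValueError):
            invariant_descriptor(coeffs, None, np.zeros(3))

    def test_parseval_consistency(self, small_cell_seq):
        """Sum of squared D_l (undoing the V^{1/3} scaling) matches the
        quadrature integral of the centered surface over the sphere within 1%."""
        frame = small_cell_seq.frames[0]
        desc, coeffs, smap = full_descriptor(frame.mesh, frame.uropod, frame.centroid)
        total = np.sum((desc.D[1:] * frame.volume ** (1 / 3)) ** 2)
        # quadrature of the band-limited surface minus its l=0 (centroid) part
        rec = reconstruct(coeffs, l_trunc=15, smap=smap, faces=frame.mesh.faces)
        w = vertex_sphere_areas(smap.unit, np.asarray(frame.mesh.faces))
        centered = np.asarray(rec.vertices) - coeffs.centroid
        oracle = float(np.sum(w * np.linalg.norm(centered, axis=1) ** 2))
        assert total == pytest.approx(oracle, rel=0.01)


class TestEllipsoidAxis:
    def test_aligned_ellipsoid(self):
        m = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        m = trimesh.Trimesh(vertices=np.asarray(m.vertices) * [3, 1, 1], faces=m.faces, process=False)
        coeffs = fit_coefficients(m, parameterize_surface(m), l_max=4)
        ax, deg = ellipsoid_axis(coeffs, uropod=np.array([-3.0, 0, 0]), centroid=np.zeros(3))
        assert not deg
        assert np.degrees(np.arccos(abs(ax[0]))) < 1.0
        assert ax[0] > 0  # oriented away from the uropod

    def test_rotation_equivariance(self):
        m = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        m = trimesh.Trimesh(vertices=np.asarray(m.vertices) * [3, 1, 1], faces=m.faces, process=False)
        R = random_rotation(7)
        mr = trimesh.Trimesh(vertices=np.asarray(m.vertices) @ R.T, faces=m.faces, process=False)
        ax0, _ = ellipsoid_axis(fit_coefficients(m, parameterize_surface(m), l_max=4))
        ax1, _ = ellipsoid_axis(fit_coefficients(mr, parameterize_surface(mr), l_max=4))
        assert min(np.linalg.norm(ax1 - R @ ax0), np.linalg.norm(ax1 + R @ ax0)) < 0.02

    def test_sphere_degenerate(self, unit_sphere):
        coeffs = fit_coefficients(unit_sphere, parameterize_surface(unit_sphere), l_max=4)
        ax, deg = ellipsoid_axis(coeffs)
        assert deg and ax is None
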