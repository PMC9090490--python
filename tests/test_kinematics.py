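import numpy as np
import pytest
import trimesh
from scipy.optimize import linprog

from morphocell.config import RunConfig
from morphocell.dip import dip_statistic, dip_test
from morphocell.kinematics import (
    axis_alignment,
    mode_accuracy,
    mode_classify,
    speed_uc,
    track_kinematics,
    velocities,
)
from morphocell.mesh_io import CellFrame, CellSequence
from morphocell.synthetic import SynthCellParams, make_cell_sequence
from morphocell.uropod import track_sequence

from conftest import random_rotation


def dip_lp_oracle(sample):
    """Exact dip by LP: minimax fit of a convex-then-concave CDF to the ecdf."""
    x = np.sort(np.asarray(sample, float))
    n = len(x)
    best = np.inf
    for k in range(-1, n):
        A_ub, b_ub = [], []

        def row(d):
            r = np.zeros(n + 1)
            for idx, val in d.items():
                r[idx] = val
            return r

        for j in range(n):
            A_ub.append(row({j: -1, n: -1})); b_ub.append(-(j + 1) / n)
            A_ub.append(row({j: 1, n: -1})); b_ub.append(j / n)
        for j in range(n - 1):
            A_ub.append(row({j: 1, j + 1: -1})); b_ub.append(0)
        for j in range(1, k):
            dx1, dx2 = x[j] - x[j - 1], x[j + 1] - x[j]
            if dx1 <= 0 or dx2 <= 0:
                continue
            A_ub.append(row({j - 1: -1 / dx1, j: 1 / dx1 + 1 / dx2, j + 1: -1 / dx2})); b_ub.append(0)
        for j in range(k + 2, n - 1):
            dx1, dx2 = x[j] - x[j - 1], x[j + 1] - x[j]
            if dx1 <= 0 or dx2 <= 0:
                continue
            A_ub.append(row({j - 1: 1 / dx1, j: -1 / dx1 - 1 / dx2, j + 1: 1 / dx2})); b_ub.append(0)
        c = np.zeros(n + 1); c[n] = 1
        res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=[(0, 1)] * n + [(0, 1)], method="highs")
        if res.status == 0:
            best = min(best, res.fun)
    return best


def linear_track_seq(n=60, dt=5.0, step=0.5, radius=2.5, seed=0):
    """Spheres of volume ~65.4 μm³ translating along +x at `step` μm/frame."""
    base = trimesh.creation.icosphere(subdivisions=2, radius=radius)
    frames = []
    for i in range(n):
        m = trimesh.Trimesh(vertices=np.asarray(base.vertices) + [step * i, 0, 0],
                            faces=base.faces, process=False)
        frames.append(CellFrame(mesh=m, t=i * dt, uropod=np.array([step * i - radius, 0.0, 0.0])))
    return CellSequence(frames=frames, dt=dt, dataset_id="track")


class TestDipStatistic:
    def test_matches_lp_oracle_on_small_samples(self):
        rng = np.random.default_rng(5)
        for trial in range(12):
            n = int(rng.integers(5, 16))
            if trial % 3 == 0:
                s = rng.random(n)
            elif trial % 3 == 1:
                s = np.concatenate([rng.normal(0, 0.5, n // 2), rng.normal(4, 0.5, n - n // 2)])
            else:
                s = rng.normal(size=n)
            assert dip_statistic(s) == pytest.approx(dip_lp_oracle(s), abs=2e-4)

    def test_bimodal_rejected_unimodal_not(self):
        rng = np.random.default_rng(0)
        bimodal = np.concatenate([rng.normal(0, 1, 300), rng.normal(8, 1, 300)])
        unimodal = rng.normal(0, 1, 600)
        _, p_b = dip_test(bimodal, n_boot=199, seed=1)
        _, p_u = dip_test(unimodal, n_boot=199, seed=1)
        assert p_b < 0.05
        assert p_u > 0.05

    def test_degenerate_samples(self):
        assert dip_statistic([1.0]) == 0.0
        assert dip_statistic([2.0, 2.0, 2.0]) == 0.0


class TestVelocities:
    def test_known_speed_arithmetic(self):
        # 0.5 μm per 5 s frame at V ≈ 65.45 -> 0.1/V^{1/3} ≈ 0.0249 s^-1;
        # use a cube-like volume of 125 by scaling radius
        seq = linear_track_seq(step=0.5, radius=3.1012)  # V ≈ 125 μm³
        _, _, v_uro, _ = velocities(seq, tau_sig=5.0)
        speed = np.linalg.norm(v_uro, axis=1)
        assert np.median(speed) == pytest.approx(0.1 / 125 ** (1 / 3), rel=0.05)

    def test_volume_scaling_halves_speed(self):
        a = linear_track_seq(step=0.5, radius=2.0)
        b = linear_track_seq(step=0.5, radius=4.0)  # volume x8
        sa = np.linalg.norm(velocities(a, 5.0)[2], axis=1)
        sb = np.linalg.norm(velocities(b, 5.0)[2], axis=1)
        assert np.median(sb) == pytest.approx(np.median(sa) / 2, rel=0.02)

    def test_window_longer_than_series_raises(self):
        seq = linear_track_seq(n=10)
        with pytest.raises(ValueError):
            velocities(seq, tau_sig=500.0)


class TestSpeedUC:
    def test_projection_parallel_perpendicular_negative(self):
        uro = np.zeros((3, 3))
        cen = np.tile([1.0, 0, 0], (3, 1))
        v = np.array([[0.02, 0, 0], [0, 0.02, 0], [-0.02, 0, 0]])
        s, undef = speed_uc(v, uro, cen)
        assert s == pytest.approx([0.02, 0.0, -0.02])
        assert not undef.any()

    def test_coincident_points_flagged(self):
        s, undef = speed_uc(np.array([[0.01, 0, 0]]), np.zeros((1, 3)), np.zeros((1, 3)))
        assert undef[0] and np.isnan(s[0])

    def test_invariance_to_rotation_and_scaling(self):
        seq = make_cell_sequence(SynthCellParams(seed=9, mesh_subdivisions=2), 60, 5.0)
        tr = track_sequence(seq)
        k0 = track_kinematics(seq, tr.tau_sig, uropod=tr.positions)
        R = random_rotation(2)
        s = 3.0
        frames = []
        for i, f in enumerate(seq.frames):
            m = trimesh.Trimesh(vertices=s * (np.asarray(f.mesh.vertices) @ R.T),
                                faces=f.mesh.faces, process=False)
            frames.append(CellFrame(mesh=m, t=f.t, uropod=s * (R @ tr.positions[i])))
        seq2 = CellSequence(frames=frames, dt=seq.dt, dataset_id="xf")
        k1 = track_kinematics(seq2, tr.tau_sig)
        good = np.isfinite(k0.speed_uc) & np.isfinite(k1.speed_uc)
        assert np.allclose(k0.speed_uc[good], k1.speed_uc[good], atol=1e-9)


class TestModeClassification:
    def test_thresholds_and_cumulative(self):
        dt = 5.0
        const = np.full(100, 0.004)
        out = mode_classify(const, dt)
        assert set(out["mode"]) == {"transition"}
        run = np.full(41, 0.005)
        out = mode_classify(run, dt, windows=(150.0,))
        # cumulative speed of 0.005 s^-1 over 200 s -> 1 cell length
        assert out["cumulative"][40] == pytest.approx(0.005 * 41 * dt, rel=1e-9)

    def test_two_state_traces_recovered(self, cfg):
        """Mode labels from the 150 s running mean match the generator's
        run/stop chain on at least 90% of decisively labeled frames."""
        accs = []
        for seed in range(3):
            seq = make_cell_sequence(SynthCellParams(seed=seed, mesh_subdivisions=2), 200, 5.0)
            tr = track_sequence(seq)
            k = track_kinematics(seq, tr.tau_sig, uropod=tr.positions, config=cfg)
            accs.append(mode_accuracy(k.mode, seq.ground_truth["modes"]))
        assert np.mean(accs) >= 0.9


class TestAxisAlignment:
    def test_runner_aligns_with_uc_axis_not_tilted_ellipsoid(self):
        seq = linear_track_seq(n=50, step=0.3)
        tilt = np.array([np.cos(np.radians(30)), np.sin(np.radians(30)), 0.0])
        axes = np.tile(tilt, (50, 1))
        rep = axis_alignment(seq, tau_sig=20.0, ellipsoid_axes=axes)
        assert len(rep) > 0
        assert rep.angle_uc_deg.median() < rep.angle_ellipsoid_deg.median()

    def test_no_passing_frames_gives_empty_report(self):
        seq = linear_track_seq(n=40, step=0.0)  # static
        rep = axis_alignment(seq, tau_sig=20.0, ellipsoid_axes=np.full((40, 3), np.nan))
        assert len(rep) == 0

    def test_velocity_agreement_filter_excludes_mismatched_frames(self):
        # uropod races ahead while the centroid stays: velocity gap > half speed
        base = trimesh.creation.icosphere(subdivisions=2, radius=2.5)
        frames = []
        for i in range(40):
            frames.append(CellFrame(mesh=base.copy(), t=i * 5.0,
                                    uropod=np.array([0.5 * i - 2.5, 0.0, 0.0])))
        seq = CellSequence(frames=frames, dt=5.0, dataset_id="mismatch")
        rep = axis_alignment(seq, tau_sig=20.0, ellipsoid_axes=np.full((40, 3), np.nan))
        assert len(rep) == 0
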