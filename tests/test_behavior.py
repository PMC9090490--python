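import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from morphocell.behavior import (
    WAVELETS,
    build_spectrogram,
    channel_entropy,
    density_and_motifs,
    embed,
    grid_entropy,
    make_bank,
    perturb_wavelet_widths,
    transition_matrix,
    width_of_influence,
)
from morphocell.config import RunConfig
from morphocell.synthetic import make_oscillatory_signal

DT = 5.0


@pytest.fixture(scope="module")
def bank():
    return make_bank(DT)


@pytest.fixture(scope="module")
def gauss3_points():
    rng = np.random.default_rng(1)
    means = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    pts = np.vstack([rng.normal(m, 0.8, size=(300, 2)) for m in means])
    return pts, means


class TestBank:
    def test_frequency_halving_roughly_doubles_width(self):
        for w in WAVELETS:
            r = width_of_influence(w, 0.01, DT) / width_of_influence(w, 0.02, DT)
            assert r == pytest.approx(2.0, rel=0.2)

    def test_widths_are_wavelet_specific(self):
        assert width_of_influence("mexh", 0.02, DT) != width_of_influence("gaus1", 0.02, DT)

    def test_lowest_frequency_respects_cap(self, bank):
        for w in WAVELETS:
            assert width_of_influence(w, bank.frequencies[w][-1], DT) <= 150.0 + 1e-9
        assert all(len(f) == 6 for f in bank.frequencies.values())
        # equally spaced, descending, top at half the Nyquist frequency
        for f in bank.frequencies.values():
            assert np.allclose(np.diff(f), f[1] - f[0])
            assert f[0] == pytest.approx(1.0 / (4 * DT))


class TestSpectrogram:
    def test_constant_input_gives_zero_response(self, bank):
        spec, _ = build_spectrogram({"x": np.full(300, 3.7)}, bank)
        assert np.max(np.abs(spec)) < 1e-8

    def test_tone_peaks_in_nearest_frequency_channel(self, bank):
        t = np.arange(600) * DT
        spec, meta = build_spectrogram({"x": np.sin(2 * np.pi * 0.01 * t)}, bank)
        rms = np.sqrt((spec**2).mean(axis=1))
        for w in WAVELETS:
            rows = [i for i, m in enumerate(meta) if m[1] == w]
            best_f = meta[rows[int(np.argmax(rms[rows]))]][2]
            ladder = bank.frequencies[w]
            assert best_f == ladder[np.argmin(np.abs(ladder - 0.01))]

    def test_time_reversal_symmetry(self, bank):
        """Mexican-hat responses are even under time reversal, Gaussian-derivative
        responses odd (up to the convolution's one-sample alignment)."""
        x = np.random.default_rng(0).normal(size=300)
        spec, meta = build_spectrogram({"x": x}, bank)
        spec_r, _ = build_spectrogram({"x": x[::-1]}, bank)
        trim = 40  # edge effects
        for i, (_, w, _f) in enumerate(meta):
            rev = spec_r[i][trim:-trim]
            sign = 1.0 if w == "mexh" else -1.0
            # the discrete convolution's alignment varies by one sample with scale
            best = min(
                np.max(np.abs(np.roll(spec[i][::-1], s)[trim:-trim] - sign * rev))
                for s in (-1, 0, 1)
            )
            assert best < 0.05 * np.abs(spec[i]).max()

    def test_short_series_raises(self, bank):
        with pytest.raises(ValueError):
            build_spectrogram({"x": np.zeros(10)}, bank)


class TestEmbedding:
    def test_two_behaviors_separate(self, bank):
        rng = np.random.default_rng(3)
        t = np.arange(400) * DT
        fast = np.sin(2 * np.pi * 0.045 * t) + 0.05 * rng.normal(size=400)
        drift = 0.5 * np.sin(2 * np.pi * 0.0008 * t) + 0.05 * rng.normal(size=400)
        spec_a, _ = build_spectrogram({"x": fast}, bank)
        spec_b, _ = build_spectrogram({"x": drift}, bank)
        keep = np.r_[30:370]  # drop wavelet edge effects
        pts = embed(np.hstack([spec_a[:, keep], spec_b[:, keep]]), seed=0)
        labels = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(pts)
        assert silhouette_score(pts, labels) > 0.5

    def test_duplicate_points_embed_nearby(self, bank):
        x = make_oscillatory_signal(225, 100, 200, DT, 0.05, seed=4)
        spec, _ = build_spectrogram({"x": x}, bank)
        doubled = np.hstack([spec, spec[:, :50]])
        pts = embed(doubled, seed=1)
        d_dup = np.linalg.norm(pts[:50] - pts[200:250], axis=1)
        from scipy.spatial.distance import pdist
        assert np.median(d_dup) < np.percentile(pdist(pts), 5)

    def test_same_seed_identical_embedding(self, bank):
        x = make_oscillatory_signal(225, 100, 150, DT, 0.05, seed=5)
        spec, _ = build_spectrogram({"x": x}, bank)
        assert np.array_equal(embed(spec, seed=7), embed(spec, seed=7))


class TestMotifs:
    def test_three_gaussians_three_motifs(self, gauss3_points):
        pts, means = gauss3_points
        mm = density_and_motifs(pts, square_dim=7, bias=20, bandwidth=0.15)
        assert mm.n_motifs == 3
        cell = mm.grid_x[1] - mm.grid_x[0]
        peaks = np.array([r["peak_xy"] for r in mm.regions])
        for m in means:
            assert np.min(np.linalg.norm(peaks - m, axis=1)) <= cell
        # every point lands in the motif around its own cluster
        assert mm.assignments.shape == (900,)
        assert set(mm.assignments) == {1, 2, 3}

    def test_pdf_integrates_to_one(self, gauss3_points):
        pts, _ = gauss3_points
        mm = density_and_motifs(pts, square_dim=7, bias=20, bandwidth=0.15)
        dx = mm.grid_x[1] - mm.grid_x[0]
        dy = mm.grid_y[1] - mm.grid_y[0]
        assert np.sum(mm.pdf) * dx * dy == pytest.approx(1.0, abs=1e-3)

    def test_uniform_points_yield_few_regions(self):
        rng = np.random.default_rng(2)
        pts = rng.random((2000, 2)) * 20
        try:
            mm = density_and_motifs(pts, square_dim=7, bias=20, bandwidth=0.15)
            assert mm.n_motifs <= 3
        except ValueError:
            pass  # no stereotypy at all is the expected outcome

    def test_maximum_bias_errors(self, gauss3_points):
        pts, _ = gauss3_points
        with pytest.raises(ValueError, match="bias"):
            density_and_motifs(pts, square_dim=7, bias=255, bandwidth=0.15)


class TestTransitions:
    def test_hand_counted_sequence(self):
        P, counts, zero = transition_matrix(np.array([1, 1, 2, 2, 1]))
        assert counts.tolist() == [[0, 1], [1, 0]]
        assert P.tolist() == [[0, 1], [1, 0]]
        assert not zero.any()

    def test_periodic_sequence_is_cyclic_permutation(self):
        P, _, _ = transition_matrix(np.array([1, 2, 3] * 10))
        assert np.allclose(P, np.roll(np.eye(3), 1, axis=1))

    def test_no_transition_across_dataset_boundary(self):
        P, counts, _ = transition_matrix([np.array([1, 2]), np.array([3, 1])])
        assert counts[1, 2] == 0  # 2 -> 3 only via the boundary; not counted
        assert counts[0, 1] == 1 and counts[2, 0] == 1

    def test_rows_sum_to_one_diagonal_zero(self):
        rng = np.random.default_rng(0)
        P, _, zero = transition_matrix(rng.integers(0, 5, 500))
        assert np.allclose(np.diag(P), 0)
        sums = P.sum(axis=1)
        assert np.allclose(sums[~zero], 1.0, atol=1e-12)


class TestGridEntropy:
    def test_deterministic_cycle_zero(self):
        cyc = np.array([[0, 0], [1, 0], [1, 1], [0, 1]] * 50, dtype=float)
        assert grid_entropy(cyc, grid=4) == 0.0

    def test_iid_uniform_approaches_log2_cells(self):
        rng = np.random.default_rng(3)
        H = grid_entropy(rng.random((100000, 2)), grid=5)
        assert H == pytest.approx(np.log2(25), rel=0.05)

    def test_entropy_nonnegative_and_needs_two_cells(self):
        with pytest.raises(ValueError):
            grid_entropy(np.zeros((50, 2)), grid=4)

    def test_oscillatory_channel_lower_entropy_than_noise(self):
        rng = np.random.default_rng(11)
        osc = make_oscillatory_signal(225, 100, 1200, DT, 0.1, seed=30)
        wn = rng.standard_normal(1200)
        h_osc = channel_entropy(osc, DT, seed=0)
        h_wn = channel_entropy(wn, DT, seed=0)
        assert h_osc < h_wn


class TestWidthSearch:
    def test_single_candidate_returned_unchanged(self):
        x = make_oscillatory_signal(225, 100, 400, DT, 0.1, seed=6)
        bank, log = perturb_wavelet_widths(x, DT, {"gaus1": [150.0]}, seed=0)
        assert bank.max_widths["gaus1"] == 150.0
        assert len(log) == 1

    def test_winner_entropy_not_above_loser(self):
        x = make_oscillatory_signal(225, 100, 700, DT, 0.1, seed=7)
        bank, log = perturb_wavelet_widths(x, DT, {"gaus1": [100.0, 150.0]}, seed=0)
        best = min(r[1] for r in log)
        chosen = [r for r in log if r[0]["gaus1"] == bank.max_widths["gaus1"]][0]
        assert chosen[1] == pytest.approx(best)

    def test_candidates_above_cap_rejected(self):
        with pytest.raises(ValueError):
            perturb_wavelet_widths(np.zeros(300), DT, {"gaus1": [200.0]}, seed=0)
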