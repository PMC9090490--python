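"""Multiscale wavelet behavioral mapping of shape dynamics.

Each PC time series is convolved with two real mother wavelets — the
Mexican hat (symmetric) and the first Gaussian derivative (antisymmetric) —
at six equally spaced frequencies per wavelet, spanning half the sampling
rate's Nyquist frequency down to the wavelet-specific frequency whose
temporal width of influence reaches a cap (150 s by default, the timescale
of behavioral organization).  Stacking the responses gives a spectrogram
whose columns describe the local multiscale morphodynamics at each time
point.  The columns are embedded in 2D with t-SNE; stereotyped motifs are
the connected high-density regions of the embedding found by kernel density
estimation plus adaptive binarization; transitions between motifs give a
Markov chain, and a grid-based Markov entropy quantifies how stereotyped a
channel's dynamics are (periodic dynamics trace closed loops and score low).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pywt
import scipy.ndimage
import scipy.signal
import scipy.stats
from sklearn.manifold import TSNE

from .config import RunConfig

log = logging.getLogger(__name__)

WAVELETS = ("mexh", "gaus1")


# ---------------------------------------------------------------------------
# wavelet bank
# ---------------------------------------------------------------------------

def _scale_for_frequency(wavelet: str, freq_hz: float, dt: float) -> float:
    return pywt.central_frequency(wavelet, precision=12) / (freq_hz * dt)


def _wavelet_kernel(wavelet: str, scale: float) -> np.ndarray:
    """Discrete wavelet kernel sampled on an exactly symmetric grid.

    Sampling the mother wavelet at symmetric offsets ±j/scale preserves the
    even (Mexican hat) / odd (Gaussian derivative) symmetry exactly at every
    scale, so time-reversal maps responses onto themselves (up to sign).
    L¹ normalization (ψ(t/s)/s) keeps the response to a unit tone independent
    of scale, so channels are comparable as a frequency bank.
    """
    psi, grid = pywt.ContinuousWavelet(wavelet).wavefun(level=12)
    half = int(np.ceil(scale * max(abs(grid[0]), grid[-1])))
    u = np.arange(-half, half + 1) / scale
    kern = np.interp(u, grid, psi, left=0.0, right=0.0)
    return kern / scale


def _cwt_response(x: np.ndarray, wavelet: str, scale: float) -> np.ndarray:
    """Same-length real wavelet response (zero-padded convolution)."""
    kern = _wavelet_kernel(wavelet, scale)
    return scipy.signal.fftconvolve(x, kern[::-1], mode="same")


def width_of_influence(wavelet: str, freq_hz: float, dt: float, settle: float = 0.01) -> float:
    """Temporal extent (s) over which a wavelet at this frequency mixes information.

    Convolves the wavelet with a long unit square pulse: a zero-mean wavelet
    responds only near the pulse edges, and the width of influence is twice
    the distance from an edge at which the response has settled to within
    ``settle`` of its interior plateau (zero).
    """
    scale = _scale_for_frequency(wavelet, freq_hz, dt)
    half = max(int(np.ceil(20 * scale)), 50)
    sig = np.zeros(6 * half)
    e1, e2 = 2 * half, 4 * half
    sig[e1:e2] = 1.0
    resp = np.abs(_cwt_response(sig, wavelet, scale))
    thr = settle * resp.max()
    interior = resp[e1 : (e1 + e2) // 2]
    above = np.nonzero(interior >= thr)[0]
    d = (above[-1] + 1) if len(above) else 0
    return 2.0 * d * dt


def _freq_for_width(wavelet: str, width_s: float, dt: float, f_high: float) -> float:
    """Lowest frequency whose width of influence stays within ``width_s``."""
    f_lo, f_hi = 1.0 / (200.0 * width_s), f_high
    if width_of_influence(wavelet, f_hi, dt) > width_s:
        return f_hi
    for _ in range(40):
        mid = np.sqrt(f_lo * f_hi)
        if width_of_influence(wavelet, mid, dt) <= width_s:
            f_hi = mid
        else:
            f_lo = mid
    return f_hi


@dataclass
class WaveletBank:
    """Two-wavelet filter bank with per-wavelet frequency ladders."""

    dt: float
    frequencies: dict            # wavelet name -> (n_freq,) Hz, descending
    max_widths: dict             # wavelet name -> cap (s) used to set the lowest rung
    n_freq: int = 6

    @property
    def rows(self) -> list:
        """(wavelet, frequency) pairs in stacking order."""
        return [(w, f) for w in self.frequencies for f in self.frequencies[w]]


def make_bank(
    dt: float,
    max_widths=None,
    config: Optional[RunConfig] = None,
) -> WaveletBank:
    """Build the standard bank: six equally spaced frequencies per wavelet.

    The top frequency has period 4·dt (half the Nyquist frequency — the
    fastest structure two samples per half-cycle can carry cleanly); the
    bottom frequency is the wavelet-specific one whose width of influence
    equals the cap (150 s default, possibly per-wavelet via ``max_widths``).
    """
    cfg = config or RunConfig()
    if max_widths is None:
        max_widths = {w: cfg.wavelet_max_width for w in WAVELETS}
    elif not isinstance(max_widths, dict):
        max_widths = {w: float(max_widths) for w in WAVELETS}
    f_high = 1.0 / (4.0 * dt)
    freqs = {}
    for w in WAVELETS:
        f_low = _freq_for_width(w, max_widths[w], dt, f_high)
        freqs[w] = np.linspace(f_high, f_low, cfg.n_frequencies)
    return WaveletBank(dt=dt, frequencies=freqs, max_widths=dict(max_widths), n_freq=cfg.n_frequencies)


def build_spectrogram(channels: dict, bank: WaveletBank) -> tuple[np.ndarray, list]:
    """Stacked real wavelet responses of the (variance-normalized) channels.

    ``channels`` maps channel name -> 1-D series (all equal length).  Each
    series is normalized to unit variance so no channel dominates the
    embedding, then convolved with every wavelet/frequency pair
    (same-length output).  Returns the (n_rows, T) spectrogram and the row
    metadata [(channel, wavelet, freq), ...].
    """
    names = list(channels)
    T = {len(np.asarray(channels[k])) for k in names}
    if len(T) != 1:
        raise ValueError("all channels must have equal length")
    T = T.pop()
    max_support = max(
        _scale_for_frequency(w, f, bank.dt) * 8 for w, f in bank.rows
    )
    if T < max_support / 2:
        raise ValueError(
            f"series of length {T} shorter than half the largest wavelet support (~{max_support:.0f} samples)"
        )
    rows = []
    meta = []
    for name in names:
        x = np.asarray(channels[name], dtype=float)
        sd = x.std()
        xn = (x - x.mean()) / (sd if sd > 0 else 1.0)
        for w in bank.frequencies:
            for f in bank.frequencies[w]:
                scale = _scale_for_frequency(w, f, bank.dt)
                rows.append(_cwt_response(xn, w, scale))
                meta.append((name, w, float(f)))
    return np.vstack(rows), meta


# ---------------------------------------------------------------------------
# embedding and motifs
# ---------------------------------------------------------------------------

def embed(
    spectrogram: np.ndarray,
    seed: int = 0,
    config: Optional[RunConfig] = None,
) -> np.ndarray:
    """t-SNE embedding of spectrogram columns to the 2D morphodynamic space.

    Standard hyperparameters: perplexity 30 (reduced automatically for small
    samples), learning rate 200, 1000 iterations, fixed seed for
    reproducibility.
    """
    cfg = config or RunConfig()
    X = np.asarray(spectrogram, dtype=float).T
    n = len(X)
    if n < 10:
        raise ValueError("need at least 10 time points to embed")
    perp = min(cfg.tsne_perplexity, (n - 1) / 3.0)
    ts = TSNE(
        n_components=2,
        perplexity=perp,
        learning_rate=cfg.tsne_learning_rate,
        max_iter=cfg.tsne_n_iter,
        init="pca",
        random_state=seed,
        method="barnes_hut" if n > 50 else "exact",
    )
    return ts.fit_transform(X)


@dataclass
class MorphoMap:
    """2D morphodynamic map: density, motif regions, assignments, transitions."""

    points: np.ndarray               # (n, 2)
    grid_x: np.ndarray               # (g,) cell-center coordinates
    grid_y: np.ndarray
    pdf: np.ndarray                  # (g, g), integrates to ~1
    image: np.ndarray                # 8-bit rescaled pdf
    region_labels: np.ndarray        # (g, g) int, 0 = background
    regions: list = field(default_factory=list)   # dicts: id, peak_xy, n_pixels
    assignments: Optional[np.ndarray] = None      # (n,) motif id per point
    transition: Optional[np.ndarray] = None
    transition_counts: Optional[np.ndarray] = None
    entropy: Optional[float] = None

    @property
    def n_motifs(self) -> int:
        return len(self.regions)


def density_and_motifs(
    points: np.ndarray,
    square_dim: int = 7,
    bias: float = 20.0,
    grid_size: int = 101,
    pad: float = 0.10,
    bandwidth: Optional[float] = None,
) -> MorphoMap:
    """KDE density over the embedding and motif regions by adaptive binarization.

    The PDF (Gaussian KDE, Scott's rule unless ``bandwidth`` is given) is
    evaluated on a ``grid_size``² raster over the padded bounding box and
    rescaled to 8-bit.  A pixel belongs to a motif when its value exceeds the
    mean over a surrounding ``square_dim``² square plus ``bias`` — adaptive
    rather than global thresholding, so density peaks joined by
    high-density 'superhighways' still separate.  Motifs are the connected
    components of kept pixels; each point is assigned to the motif whose
    region is nearest to its grid cell.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 100:
        raise ValueError("need at least 100 embedded points")
    kde = scipy.stats.gaussian_kde(pts.T, bw_method=bandwidth)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = hi - lo
    lo = lo - pad * span
    hi = hi + pad * span
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    pdf = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(grid_size, grid_size)

    img = 255.0 * pdf / pdf.max()
    local_mean = scipy.ndimage.uniform_filter(img, size=square_dim, mode="reflect")
    keep = img > local_mean + bias
    labels, n_regions = scipy.ndimage.label(keep)
    if n_regions == 0:
        raise ValueError("no motif regions found; reduce the binarization bias")

    regions = []
    for rid in range(1, n_regions + 1):
        mask = labels == rid
        flat = np.where(mask, pdf, -np.inf)
        pi, pj = np.unravel_index(np.argmax(flat), pdf.shape)
        regions.append({"id": rid, "peak_xy": (float(gx[pi]), float(gy[pj])), "n_pixels": int(mask.sum())})

    # nearest-region lookup per grid cell, then per point
    dist, (ii, jj) = scipy.ndimage.distance_transform_edt(labels == 0, return_indices=True)
    nearest = labels[ii, jj]
    pi = np.clip(np.searchsorted(gx, pts[:, 0]) - 0, 0, grid_size - 1)
    pj = np.clip(np.searchsorted(gy, pts[:, 1]) - 0, 0, grid_size - 1)
    assignments = nearest[pi, pj]

    return MorphoMap(
        points=pts,
        grid_x=gx,
        grid_y=gy,
        pdf=pdf,
        image=img,
        region_labels=labels,
        regions=regions,
        assignments=assignments,
    )


def transition_matrix(label_sequences) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Motif transition probabilities pooled over datasets.

    ``label_sequences`` is one label array or a list of them (one per
    dataset; transitions never cross dataset boundaries).  A transition is
    counted only when the label changes, so the diagonal is exactly zero.
    Returns (matrix, counts, zero_row_flags); rows with no outgoing
    transitions are flagged and left as zeros.
    """
    if isinstance(label_sequences, np.ndarray) and label_sequences.ndim == 1:
        label_sequences = [label_sequences]
    all_labels = np.unique(np.concatenate([np.asarray(s) for s in label_sequences]))
    index = {lab: k for k, lab in enumerate(all_labels)}
    K = len(all_labels)
    counts = np.zeros((K, K))
    for seq in label_sequences:
        seq = np.asarray(seq)
        for a, b in zip(seq[:-1], seq[1:]):
            if a != b:
                counts[index[a], index[b]] += 1
    rowsum = counts.sum(axis=1)
    zero_rows = rowsum == 0
    if zero_rows.any():
        log.warning("motif(s) %s have no outgoing transitions", all_labels[zero_rows])
    P = np.divide(counts, rowsum[:, None], out=np.zeros_like(counts), where=rowsum[:, None] > 0)
    return P, counts, zero_rows


# ---------------------------------------------------------------------------
# grid Markov entropy
# ---------------------------------------------------------------------------

def _stationary(P: np.ndarray) -> np.ndarray:
    w, vl = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(vl[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def grid_entropy(
    point_sequences,
    grid: int = 20,
    on_change: bool = False,
) -> float:
    """Markov-chain entropy (bits) of trajectories on a grid over the map.

    Points are assigned to a ``grid`` x ``grid`` raster over their bounding
    box; consecutive samples within each dataset define a Markov chain over
    visited cells (self-transitions retained unless ``on_change``).  The
    entropy is −Σ_i π_i Σ_j p_ij log2 p_ij with π the stationary
    distribution.  A reducible chain is restricted to its largest strongly
    connected component (with a warning).  Deterministic dynamics give 0.
    """
    if isinstance(point_sequences, np.ndarray) and point_sequences.ndim == 2:
        point_sequences = [point_sequences]
    allpts = np.vstack(point_sequences)
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    pairs = []
    for pts in point_sequences:
        pts = np.asarray(pts, dtype=float)
        ij = np.minimum((grid * (pts - lo) / span).astype(int), grid - 1)
        cells = ij[:, 0] * grid + ij[:, 1]
        a, b = cells[:-1], cells[1:]
        if on_change:
            m = a != b
            a, b = a[m], b[m]
        pairs.append(np.column_stack([a, b]))
    pairs = np.vstack(pairs)
    if len(pairs) == 0:
        raise ValueError("no transitions")
    cells = np.unique(pairs)
    if len(cells) < 2:
        raise ValueError("need at least 2 occupied grid cells")
    remap = {c: k for k, c in enumerate(cells)}
    K = len(cells)
    counts = np.zeros((K, K))
    np.add.at(counts, (np.vectorize(remap.get)(pairs[:, 0]), np.vectorize(remap.get)(pairs[:, 1])), 1)

    G = nx.DiGraph()
    G.add_nodes_from(range(K))
    G.add_edges_from(zip(*np.nonzero(counts)))
    sccs = sorted(nx.strongly_connected_components(G), key=len, reverse=True)
    if len(sccs) > 1:
        log.warning("reducible transition chain: restricting to largest SCC (%d of %d states)", len(sccs[0]), K)
    keep = sorted(sccs[0])
    counts = counts[np.ix_(keep, keep)]
    rowsum = counts.sum(axis=1)
    pos = rowsum > 0
    counts = counts[np.ix_(pos, pos)]
    rowsum = counts.sum(axis=1)
    P = counts / rowsum[:, None]
    pi = _stationary(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
    H = -float(np.sum(pi[:, None] * P * lp))
    return max(H, 0.0)


def channel_entropy(
    series: np.ndarray,
    dt: float,
    seed: int = 0,
    bank: Optional[WaveletBank] = None,
    config: Optional[RunConfig] = None,
    grid: Optional[int] = None,
    on_change: bool = False,
) -> float:
    """Marginal morphodynamic entropy of one channel (wavelet → t-SNE → grid)."""
    cfg = config or RunConfig()
    bank = bank or make_bank(dt, config=cfg)
    spec, _ = build_spectrogram({"x": series}, bank)
    pts = embed(spec, seed=seed, config=cfg)
    return grid_entropy(pts, grid=grid or cfg.entropy_grid, on_change=on_change)


def perturb_wavelet_widths(
    series: np.ndarray,
    dt: float,
    candidates: dict,
    seed: int = 0,
    config: Optional[RunConfig] = None,
) -> tuple[WaveletBank, list]:
    """Local search over per-wavelet maximum widths minimizing grid entropy.

    ``candidates`` maps wavelet name -> iterable of candidate maximum widths
    (s), each at most the configured cap.  Every combination is evaluated by
    the marginal-entropy pipeline on ``series``; the bank with the lowest
    entropy wins, ties going to the smallest total width.  Returns the
    winning bank and the search log [(widths, entropy), ...].
    """
    cfg = config or RunConfig()
    for w, cand in candidates.items():
        if any(c > cfg.wavelet_max_width for c in cand):
            raise ValueError(f"candidate width above the {cfg.wavelet_max_width}s cap for {w}")
    names = list(candidates)
    combos = list(itertools.product(*[sorted(candidates[w]) for w in names]))
    results = []
    for combo in combos:
        widths = {w: float(c) for w, c in zip(names, combo)}
        for w in WAVELETS:
            widths.setdefault(w, cfg.wavelet_max_width)
        bank = make_bank(dt, max_widths=widths, config=cfg)
        H = channel_entropy(series, dt, seed=seed, bank=bank, config=cfg)
        results.append((widths, H))
    tol = 1e-9
    best_H = min(r[1] for r in results)
    ties = [r for r in results if r[1] <= best_H + tol]
    best = min(ties, key=lambda r: sum(r[0].values()))
    return make_bank(dt, max_widths=best[0], config=cfg), results
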