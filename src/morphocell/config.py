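"""Run-wide configuration: every tunable constant of the pipeline in one place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Pipeline constants with their standard defaults.

    Attributes
    ----------
    l_max : highest spherical-harmonic degree retained in the descriptor.
    d0_factor : prefactor of the polarization descriptor
        D0 = d0_factor * ||uropod - centroid|| / V^(1/3).  The default sqrt(3)/2
        combines the three coordinate functions summed in quadrature (sqrt 3)
        with the factor 1/2 from coefficients spanning twice their magnitude.
    double_count_m : double the m>0 coefficient power so the descriptor
        represents the omitted negative orders of the real expansion.
    run_threshold, stop_threshold : bounds (s^-1, scale-invariant speed) on the
        long-window running-mean speed separating run and stop migration modes.
    mode_window : running-mean window (s) at which run/stop bimodality emerges.
    tau_sig_cap : maximum significance timescale (s); datasets hitting the cap
        are flagged near-stationary.
    highpass_hz : Butterworth high-pass cutoff for detrending.
    snr_min : minimum sd(signal)/sigma_PC for a PC channel to enter
        time-series analyses.
    wavelet_max_width : cap (s) on the width of influence of the slowest
        wavelet in the behavioral bank.
    binarize_square, binarize_bias : adaptive-binarization local-square size and
        bias for motif extraction on the pooled map.
    binarize_square_run, binarize_bias_run : same, for run-mode-only maps.
    entropy_grid : cells per side of the grid used for Markov-chain entropy.
    seed : master seed for every stochastic step (t-SNE, synthesis).
    """

    l_max: int = 15
    d0_factor: float = math.sqrt(3.0) / 2.0
    double_count_m: bool = True
    run_threshold: float = 0.005
    stop_threshold: float = 0.0025
    mode_window: float = 150.0
    windows: tuple = (10.0, 50.0, 150.0, 300.0)
    tau_sig_cap: float = 100.0
    perturb_angle_deg: float = 20.0
    curvature_neighbors: int = 15
    chord_center: str = "curvature"
    highpass_hz: float = 0.0025
    butter_order: int = 2
    snr_min: float = 2.5
    wavelet_max_width: float = 150.0
    n_frequencies: int = 6
    f_high_rule: str = "quarter_sampling"
    tsne_perplexity: float = 30.0
    tsne_learning_rate: float = 200.0
    tsne_n_iter: int = 1000
    kde_grid: int = 101
    kde_bandwidth: float | None = 0.12  # gaussian_kde factor; None = Scott's rule
    binarize_square: int = 7
    binarize_bias: float = 20.0
    binarize_square_run: int = 15
    binarize_bias_run: float = 50.0
    entropy_grid: int = 20
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in names}
        if "windows" in kwargs:
            kwargs["windows"] = tuple(kwargs["windows"])
        return cls(**kwargs)
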