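"""PCA shape space over pooled invariant descriptors.

The 16-dimensional descriptor vectors {D_l} pooled over all datasets are
decomposed by an eigendecomposition of their 16x16 covariance matrix (no
per-feature standardization: the descriptors share units).  Three components
typically suffice to capture the bulk of shape variance in migrating
amoeboid cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class ShapeSpace:
    """Fitted PCA basis: mean descriptor, orthonormal loadings, variance shares."""

    mean: np.ndarray                 # (d,)
    loadings: np.ndarray             # (d, d) columns = PCs, orthonormal
    explained_variance_ratio: np.ndarray  # (d,) non-increasing, sums to 1
    scores: np.ndarray               # (n, d) per-frame PC coordinates
    n_components: int = 3

    def project(self, descriptors: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(descriptors) - self.mean) @ self.loadings

    def top_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_components]


def _orient_loadings(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign: D1 component >= 0, tie-break on D0 component."""
    out = loadings.copy()
    for k in range(out.shape[1]):
        v = out[:, k]
        key = v[1] if abs(v[1]) > 1e-12 else v[0]
        if key < 0:
            out[:, k] = -v
    return out


def fit_pca(descriptors, n_components: int = 3) -> ShapeSpace:
    """Fit the shape space from a descriptor table or array.

    ``descriptors`` is an (n, d) array or a DataFrame holding D0..D{d-1}
    columns; requires n > d frames pooled across datasets.
    """
    if isinstance(descriptors, pd.DataFrame):
        cols = [c for c in descriptors.columns if c.startswith("D") and c[1:].isdigit()]
        cols = sorted(cols, key=lambda c: int(c[1:]))
        X = descriptors[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(descriptors, dtype=float)
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more than {d} frames to fit a {d}-dimensional shape space, got {n}")
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(X)
    loadings = _orient_loadings(pca.components_.T)
    scores = (X - pca.mean_) @ loadings
    return ShapeSpace(
        mean=pca.mean_,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
        n_components=n_components,
    )


def invert_pc(space: ShapeSpace, pc_index: int, value: float) -> np.ndarray:
    """Descriptor vector at coordinate ``value`` along one PC, others at zero."""
    return space.mean + value * space.loadings[:, pc_index]


def representative_frames(space: ShapeSpace, n_bins: int = 7, selection: str = "norm"):
    """Representative frame per equal-length bin along each of the top PCs.

    For each PC the score range is split into ``n_bins`` equal-length bins;
    within each nonempty bin the frame minimizing the size of the other top
    PCs is picked (``selection='norm'``: Euclidean norm of the other scores;
    ``'sum'``: sum of absolute values).  Empty bins are reported as None.
    """
    scores = space.top_scores()
    k = scores.shape[1]
    result: dict[int, list] = {}
    for pc in range(k):
        s = scores[:, pc]
        edges = np.linspace(s.min(), s.max(), n_bins + 1)
        others = np.delete(scores, pc, axis=1)
        if selection == "norm":
            size = np.linalg.norm(others, axis=1)
        elif selection == "sum":
            size = np.abs(others).sum(axis=1)
        else:
            raise ValueError("selection must be 'norm' or 'sum'")
        chosen: list = []
        for b in range(n_bins):
            hi = edges[b + 1] + (1e-12 if b == n_bins - 1 else 0.0)
            in_bin = np.where((s >= edges[b]) & (s < hi))[0]
            chosen.append(None if len(in_bin) == 0 else int(in_bin[np.argmin(size[in_bin])]))
        result[pc] = chosen
    return result


def snr_flags(space: ShapeSpace, sigma_pc: Sequence[float], snr_min: float = 2.5,
              dataset_index: Optional[np.ndarray] = None) -> np.ndarray:
    """Low-SNR flags per top PC: sd(score series) / sigma_PC below ``snr_min``.

    ``dataset_index`` restricts the signal sd to one dataset's rows; default
    uses all scores.
    """
    scores = space.top_scores()
    if dataset_index is not None:
        scores = scores[dataset_index]
    sds = scores.std(axis=0, ddof=1)
    sigma = np.asarray(sigma_pc, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(sigma > 0, sds / np.maximum(sigma, 1e-300), np.inf)
    return ratio < snr_min
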