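"""Hartigan's dip statistic and dip test of unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF,

    dip = min_{G unimodal} sup_x |F_n(x) - G(x)|.

It is computed here by bisection on the distance t: for a given t the
pointwise admissible band for G at the i-th order statistic is
[(i+1)/n - t, i/n + t] (clipped to [0, 1]), and a unimodal G within the band
exists iff the sample splits into a prefix admitting a convex CDF piece and
a suffix admitting a concave piece.  Convex-piece feasibility over a prefix
is checked incrementally with the greatest convex minorant of the upper
band; the minorant must stay above the lower band.  The result matches a
linear-programming minimax fit (see the test suite) to the bisection
tolerance.

The null distribution of the dip is taken, as is conventional, from uniform
samples of the same size (the statistic is asymptotically least favourable
there among unimodal laws), so p-values come from Monte Carlo.
"""

from __future__ import annotations

import numpy as np


def _max_convex_prefix(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> int:
    """Largest k such that a convex function f(x_i) in [lo_i, hi_i] exists for i <= k.

    Uses the greatest convex minorant of the upper bounds: the maximal convex
    candidate.  Returns -1 if even the first point is infeasible.
    """
    n = len(x)
    if n == 0 or lo[0] > hi[0]:
        return -1
    hull = [0]  # indices of the gcm of (x, hi)
    for j in range(1, n):
        if lo[j] > hi[j]:
            return j - 1
        # pop while the hull loses convexity with the new point
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (hi[j] - hi[b]) * (x[b] - x[a]) < (hi[b] - hi[a]) * (x[j] - x[b]):
                hull.pop()
            else:
                break
        a = hull[-1]
        # the new segment a -> j replaces the minorant over (a, j); it must
        # stay above lo there (at the hull points themselves gcm == hi >= lo)
        if j - a > 1:
            xs = x[a + 1 : j]
            seg = hi[a] + (hi[j] - hi[a]) * (xs - x[a]) / (x[j] - x[a])
            if np.any(seg < lo[a + 1 : j] - 1e-12):
                return j - 1
        hull.append(j)
    return n - 1


def _min_concave_suffix(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> int:
    """Smallest j such that a concave function within the bands exists for i >= j."""
    # mirror the data: concave on [j, n) <=> convex on the reversed, negated axis
    xr = -x[::-1]
    lo_r = 1.0 - hi[::-1]
    hi_r = 1.0 - lo[::-1]
    k = _max_convex_prefix(xr, lo_r, hi_r)
    n = len(x)
    return n - 1 - k if k >= 0 else n


def _feasible(x: np.ndarray, n: int, t: float) -> bool:
    i = np.arange(n)
    lo = np.clip((i + 1) / n - t, 0.0, 1.0)
    hi = np.clip(i / n + t, 0.0, 1.0)
    k_conv = _max_convex_prefix(x, lo, hi)
    if k_conv == n - 1:
        return True
    j_conc = _min_concave_suffix(x, lo, hi)
    return j_conc <= k_conv + 1


def dip_statistic(sample, tol: float = 1e-6) -> float:
    """Hartigan's dip of a 1-D sample (0 for n < 2 or all-equal samples)."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return 0.0
    # collapse ties: work with unique support but keep the ecdf heights by
    # treating duplicates through the band (duplicates make bands at equal x;
    # keep the tightest)
    lo_t, hi_t = 0.0, 0.25
    if _feasible(x, n, lo_t + 1e-15):
        return 0.0
    while hi_t - lo_t > tol:
        mid = 0.5 * (lo_t + hi_t)
        if _feasible(x, n, mid):
            hi_t = mid
        else:
            lo_t = mid
    return 0.5 * (lo_t + hi_t)


_NULL_CACHE: dict = {}


def dip_test(sample, n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and Monte Carlo p-value against the uniform null.

    Returns ``(dip, p)``; small p rejects unimodality.  The null draws
    depend only on the sample size, so they are cached per (n, n_boot, seed).
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    d = dip_statistic(x)
    if n < 4:
        return d, 1.0
    key = (n, n_boot, seed)
    boot = _NULL_CACHE.get(key)
    if boot is None:
        rng = np.random.default_rng(seed)
        boot = np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])
        _NULL_CACHE[key] = boot
    p = float((np.sum(boot >= d) + 1) / (n_boot + 1))
    return d, p
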