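"""Hartigan & Hartigan's dip statistic for unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and the class of unimodal distribution functions. It is computed with the
classic iterative algorithm: repeatedly form the greatest convex minorant
(g.c.m.) and least concave majorant (l.c.m.) of the empirical CDF on the
current modal interval, shrink the interval to where they are furthest apart,
and accumulate the largest discrepancy outside it. The p-value is calibrated
by Monte Carlo against the uniform null (the asymptotically least favourable
unimodal distribution).
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue"]


def _gcm(cdf: np.ndarray, x: np.ndarray):
    """Greatest convex minorant touch points of points (x_i, cdf_i).

    Returns the indices (into ``x``) of the lower convex hull, left to right.
    """
    hull = [0]
    for i in range(1, len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # pop b if it lies above segment a->i
            if (cdf[b] - cdf[a]) * (x[i] - x[a]) >= (cdf[i] - cdf[a]) * (x[b] - x[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _lcm(cdf: np.ndarray, x: np.ndarray):
    """Least concave majorant touch points, left to right."""
    hull = [0]
    for i in range(1, len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (cdf[b] - cdf[a]) * (x[i] - x[a]) <= (cdf[i] - cdf[a]) * (x[b] - x[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _interp_on(x, knots_idx, values, at_idx):
    """Piecewise-linear interpolation of (x[knots], values[knots]) at x[at]."""
    xs = x[knots_idx]
    vs = values[knots_idx]
    return np.interp(x[at_idx], xs, vs)


def dip_statistic(sample: np.ndarray) -> float:
    """Hartigan's dip statistic of a 1-D sample.

    Bounds: ``1/(2n) <= dip <= 1/4`` for samples with at least two distinct
    values; degenerate (constant) samples return 0.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    # tied values are separated by an infinitesimal slope; the dip is
    # continuous under this perturbation (an atom at the mode absorbs the
    # collapsed jump in the limit)
    if np.any(np.diff(x) == 0):
        x = x + np.arange(n) * (x[-1] - x[0]) * 1e-9
    # Empirical CDF: F(x_i) = i/n (value), F(x_i-) = (i-1)/n (left limit).
    F = np.arange(1, n + 1) / n
    Fm = np.arange(0, n) / n

    low, high = 0, n - 1
    D = 1.0 / n  # twice the attainable lower bound; dip returned is D/2

    while True:
        idx = np.arange(low, high + 1)
        xs = x[idx]
        # g.c.m. of the left limits, l.c.m. of the values on [low, high]
        gcm_local = _gcm(Fm[idx], xs)
        lcm_local = _lcm(F[idx], xs)
        gcm = [low + i for i in gcm_local]
        lcm = [low + i for i in lcm_local]

        # largest distance between the two hulls, evaluated at both touch sets
        g_at_l = np.interp(x[lcm], x[gcm], Fm[gcm])
        l_at_g = np.interp(x[gcm], x[lcm], F[lcm])
        d_candidates = []
        for j, i_l in enumerate(lcm):
            d_candidates.append((F[i_l] - g_at_l[j], i_l, "lcm"))
        for j, i_g in enumerate(gcm):
            d_candidates.append((l_at_g[j] - Fm[i_g], i_g, "gcm"))
        d, i_at, which = max(d_candidates, key=lambda t: t[0])

        if d <= D:
            return D / 2.0

        # new modal interval: hull knots bracketing the worst point
        if which == "lcm":
            new_low = max(i for i in gcm if x[i] <= x[i_at])
            new_high = i_at
        else:
            new_low = i_at
            new_high = min(i for i in lcm if x[i] >= x[i_at])

        # accumulate the sup distance of F to the hulls outside the new interval
        left_knots = [i for i in gcm if i <= new_low]
        if len(left_knots) >= 2:
            seg = np.arange(low, new_low + 1)
            fit = np.interp(x[seg], x[left_knots], Fm[left_knots])
            D = max(D, float(np.max(F[seg] - fit)), float(np.max(fit - Fm[seg])))
        right_knots = [i for i in lcm if i >= new_high]
        if len(right_knots) >= 2:
            seg = np.arange(new_high, high + 1)
            fit = np.interp(x[seg], x[right_knots], F[right_knots])
            D = max(D, float(np.max(fit - Fm[seg])), float(np.max(F[seg] - fit)))

        if new_low == low and new_high == high:
            return D / 2.0
        low, high = new_low, new_high
        if high - low < 1:
            return D / 2.0


def dip_pvalue(
    dip: float, n: int, n_boot: int = 500, seed: int | None = 0
) -> float:
    """Monte-Carlo p-value of a dip statistic under the uniform null.

    Draws ``n_boot`` uniform samples of size ``n`` and returns the fraction
    with a dip at least as large as the observed one (with the +1 continuity
    correction).
    """
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        if dip_statistic(rng.uniform(size=n)) >= dip:
            count += 1
    return (count + 1) / (n_boot + 1)
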