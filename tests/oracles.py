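"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check.
"""

import numpy as np
from scipy.optimize import linprog


def dip_lp(sample: np.ndarray) -> float:
    """Exact dip statistic via linear programming (small n).

    The optimal unimodal CDF approximating an empirical CDF in sup norm can
    be taken piecewise linear with knots at the (sorted, distinct) data
    points and at most one jump, located at the mode. For a fixed mode index
    k, minimizing the band half-width eps subject to the band constraints,
    monotonicity, convexity left of the mode and concavity right of it is a
    linear program in the node values, left limits and eps; the dip is the
    minimum over k.
    """
    x = np.sort(np.asarray(sample, float))
    n = x.size
    assert len(np.unique(x)) == n, "oracle assumes distinct points"
    dx = np.diff(x)
    best = np.inf
    nv = 2 * n + 1
    iv = lambda i: i
    iw = lambda i: n + i
    ie = 2 * n
    for k in range(n):
        A_ub, b_ub, A_eq, b_eq = [], [], [], []

        def ub(coeffs, b):
            row = np.zeros(nv)
            for j, c in coeffs:
                row[j] += c
            A_ub.append(row)
            b_ub.append(b)

        def eq(coeffs, b):
            row = np.zeros(nv)
            for j, c in coeffs:
                row[j] += c
            A_eq.append(row)
            b_eq.append(b)

        ub([(iw(0), 1), (ie, -1)], 0.0)  # before x_0: G <= eps
        for i in range(n - 1):
            Fi = (i + 1) / n
            ub([(iv(i), 1), (ie, -1)], Fi)
            ub([(iv(i), -1), (ie, -1)], -Fi)
            ub([(iw(i + 1), 1), (ie, -1)], Fi)
            ub([(iw(i + 1), -1), (ie, -1)], -Fi)
        ub([(iv(n - 1), -1), (ie, -1)], -1.0)  # after x_{n-1}: G >= 1 - eps
        for i in range(n):
            if i == k:
                ub([(iw(i), 1), (iv(i), -1)], 0.0)  # upward jump at the mode
            else:
                eq([(iv(i), 1), (iw(i), -1)], 0.0)
        for i in range(n - 1):  # slopes >= 0
            ub([(iw(i + 1), -1), (iv(i), 1)], 0.0)
        for i in range(n - 2):
            si = [(iw(i + 1), 1 / dx[i]), (iv(i), -1 / dx[i])]
            sj = [(iw(i + 2), 1 / dx[i + 1]), (iv(i + 1), -1 / dx[i + 1])]
            if i + 1 <= k - 1:  # convex left of the mode
                ub(si + [(j, -c) for j, c in sj], 0.0)
            if i >= k:  # concave right of it
                ub(sj + [(j, -c) for j, c in si], 0.0)
        c = np.zeros(nv)
        c[ie] = 1.0
        res = linprog(
            c,
            A_ub=np.array(A_ub),
            b_ub=np.array(b_ub),
            A_eq=np.array(A_eq) if A_eq else None,
            b_eq=np.array(b_eq) if b_eq else None,
            bounds=[(0, 1)] * (2 * n) + [(0, 0.5)],
            method="highs",
        )
        if res.success:
            best = min(best, res.fun)
    return best


def fft_mask_filter(x: np.ndarray, rate: float, low: float, high: float, order: int = 4):
    """Frequency-domain oracle for the zero-phase Butterworth band-pass: apply
    the squared design magnitude response as a real mask."""
    from scipy import signal as sps

    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(len(x), 1 / rate)
    b, a = sps.butter(order, [low, high], btype="bandpass", fs=rate)
    _, h = sps.freqz(b, a, worN=f * 2 * np.pi / rate)
    return np.fft.irfft(X * np.abs(h) ** 2, len(x))


def lattice_neighbor_count(radius_units: float) -> int:
    """Brute-force count of nonzero integer offsets within a Euclidean radius."""
    r = int(np.ceil(radius_units))
    count = 0
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            for k in range(-r, r + 1):
                if (i, j, k) != (0, 0, 0) and i * i + j * j + k * k <= radius_units**2 + 1e-9:
                    count += 1
    return count
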