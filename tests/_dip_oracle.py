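"""Brute-force oracle for Hartigan's dip statistic.

Independent of the package's envelope-based algorithm: the dip is computed
directly from its definition, ``min_G sup_x |F_n(x) - G(x)|`` over unimodal
CDFs G, by solving one small linear program per candidate mode position and
taking the minimum.

A unimodal CDF is nondecreasing, convex left of its mode, concave right of
it, with limits 0 and 1; an atom is allowed only at the mode.  Because the
ECDF is a staircase, the sup-distance constraints bind only at the sample's
distinct values (lower band at an interval's left edge, upper band at its
right edge), so G can be represented by its values at the distinct points,
one extra value for the left limit at the mode, and the unknown distance
eps.  Minimising eps subject to band, monotonicity and shape constraints is
a linear program.  The optimal mode may always be placed at a data point or
outside the data range (an interior mode between two points can be slid to
a neighbouring point by replacing that span of G with its chord), so the
candidate modes are the distinct values plus the fully-convex and
fully-concave cases.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _solve(c, A_ub, b_ub, bounds, n_var):
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds,
                  method="highs")
    if not res.success:
        return np.inf
    return float(res.fun)


def _mode_lp(t: np.ndarray, c: np.ndarray, mode: int | str) -> float:
    """Minimal sup-distance for a fixed mode placement.

    ``mode`` is a knot index (atom allowed there), or "convex" / "concave"
    for a mode beyond the right / left end of the data.
    """
    k = t.size
    cprev = np.concatenate([[0.0], c[:-1]])  # ECDF level just left of each knot

    # variables: g_0..g_{k-1}, [vleft], eps  (vleft = G(mode-), knot modes only)
    knot_mode = isinstance(mode, (int, np.integer))
    nv = k + 2 if knot_mode else k + 1
    i_eps = nv - 1
    i_vl = k if knot_mode else None

    A, b = [], []

    def row(coefs: dict[int, float], rhs: float) -> None:
        r = [0.0] * nv
        for i, v in coefs.items():
            r[i] += v
        A.append(r)
        b.append(rhs)

    # lower band at every knot: g_i >= c_i - eps
    for i in range(k):
        row({i: -1.0, i_eps: -1.0}, -c[i])
    # upper band via left-continuity: g_i <= cprev_i + eps, except at a knot
    # mode where the left limit vleft carries that constraint instead
    for i in range(k):
        if knot_mode and i == mode:
            row({i_vl: 1.0, i_eps: -1.0}, cprev[i])
        else:
            row({i: 1.0, i_eps: -1.0}, cprev[i])
    # monotonicity
    for i in range(k - 1):
        row({i: 1.0, i + 1: -1.0}, 0.0)
    if knot_mode:
        if mode > 0:
            row({mode - 1: 1.0, i_vl: -1.0}, 0.0)  # g_{j-1} <= vleft
        row({i_vl: 1.0, mode: -1.0}, 0.0)          # vleft <= g_j (jump up ok)

    # shape constraints: slopes nondecreasing on the convex side,
    # nonincreasing on the concave side
    def left_points():
        if mode == "convex":
            return [(t[i], i) for i in range(k)]
        if mode == "concave":
            return []
        pts = [(t[i], i) for i in range(mode)]
        pts.append((t[mode], i_vl))
        return pts

    def right_points():
        if mode == "concave":
            return [(t[i], i) for i in range(k)]
        if mode == "convex":
            return []
        return [(t[i], i) for i in range(mode, k)]

    for pts, sign in ((left_points(), +1.0), (right_points(), -1.0)):
        for (xa, ia), (xb, ib), (xc, ic) in zip(pts, pts[1:], pts[2:]):
            d1, d2 = xb - xa, xc - xb
            # sign * [ (y_b - y_a)/d1 - (y_c - y_b)/d2 ] <= 0
            row({ia: -sign / d1, ib: sign / d1 + sign / d2, ic: -sign / d2}, 0.0)

    cost = [0.0] * nv
    cost[i_eps] = 1.0
    bounds = [(0.0, 1.0)] * (nv - 1) + [(0.0, 1.0)]
    return _solve(cost, A, b, bounds, nv)


def dip_bruteforce(x) -> float:
    """Dip statistic by direct sup-distance minimisation (small samples)."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    if n < 2:
        raise ValueError("need n >= 2")
    t, counts = np.unique(xs, return_counts=True)
    if t.size == 1:
        return 0.5 / n
    c = np.cumsum(counts) / n
    best = min(_mode_lp(t, c, "convex"), _mode_lp(t, c, "concave"))
    for j in range(t.size):
        best = min(best, _mode_lp(t, c, j))
    return best
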