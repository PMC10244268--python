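"""Hartigan & Hartigan's dip statistic for unimodality.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal CDF (convex increasing up to the mode,
concave increasing after it; an atom is permitted at the mode).

`dip_statistic` uses the iterative modal-interval construction: compute the
greatest convex minorant (GCM) and least concave majorant (LCM) of F_n on the
current interval, find the largest gap between them, narrow the interval to
the hull touchpoints bracketing that gap, and accumulate the deviation of F_n
from the minorant left of the interval and from the majorant right of it.
When the within-interval hull gap no longer exceeds the accumulated outside
deviation, the dip is half that deviation (a unimodal CDF can split every
band symmetrically).  O(n log n) after sorting in practice.

`dip_statistic_lp` solves the defining minimax problem directly as a family
of linear programs — one per candidate mode position, with the mode's CDF
left limit as an explicit variable so that the convex/concave chord
constraints are modelled exactly — and serves as an independent cross-check
on small samples.  Modes interior to inter-point gaps are scanned on a fine
grid, so its value is exact up to grid refinement there.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_statistic_lp"]


def _lower_hull(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    """Indices of the lower convex hull of points with strictly increasing x."""
    hull: list[int] = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (xs[b] - xs[a]) * (ys[i] - ys[a]) - (ys[b] - ys[a]) * (xs[i] - xs[a]) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _upper_hull(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    """Indices of the upper concave hull of points with strictly increasing x."""
    hull: list[int] = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (xs[b] - xs[a]) * (ys[i] - ys[a]) - (ys[b] - ys[a]) * (xs[i] - xs[a]) >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def dip_statistic(values) -> float:
    """Hartigan's dip statistic D of a 1-d sample.

    Satisfies 1/(2n) <= D <= 0.25 for samples with at least two distinct
    values; a constant sample has dip 0.  Duplicating every observation
    leaves D unchanged.

    Parameters
    ----------
    values : array-like
        Sample of at least 2 observations.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("dip statistic requires at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic requires finite values")
    if x[0] == x[-1]:
        return 0.0

    # Compress ties: per distinct value, the count of observations strictly
    # below it (binding for the convex minorant) and at or below it (binding
    # for the concave majorant).  All deviations are kept in count units and
    # rescaled at the end.
    xu, first = np.unique(x, return_index=True)
    left = first.astype(float)
    right = np.append(first[1:], n).astype(float)

    lo, hi = 0, xu.size - 1
    best = 1.0  # floor: one F_n jump always separates the hulls

    for _ in range(xu.size + 2):
        xs = xu[lo:hi + 1]
        g_idx = _lower_hull(xs, left[lo:hi + 1])
        l_idx = _upper_hull(xs, right[lo:hi + 1])
        gx, gy = xs[g_idx], left[lo:hi + 1][g_idx]
        lx, ly = xs[l_idx], right[lo:hi + 1][l_idx]

        # largest majorant-minorant gap, checked at every touchpoint
        gap_l = ly - np.interp(lx, gx, gy)
        gap_g = np.interp(gx, lx, ly) - gy
        i_l = int(np.argmax(gap_l))
        i_g = int(np.argmax(gap_g))
        if gap_l[i_l] >= gap_g[i_g]:
            d = float(gap_l[i_l])
            new_hi = lo + l_idx[i_l]
            k = int(np.searchsorted(gx, lx[i_l], side="right")) - 1
            new_lo = lo + g_idx[k]
        else:
            d = float(gap_g[i_g])
            new_lo = lo + g_idx[i_g]
            k = int(np.searchsorted(lx, gx[i_g], side="left"))
            new_hi = lo + l_idx[k]

        if d <= best:
            break

        # Deviation of F_n above the minorant on [lo, new_lo] and below the
        # majorant on [new_hi, hi].  The terminals are mode candidates: only
        # the CDF's left (resp. right) limit binds there, so a tie run at a
        # terminal contributes nothing — measure interior points only.
        if new_lo > lo:
            seg = slice(lo, new_lo)
            dev_l = float(np.max(right[seg] - np.interp(xu[seg], gx, gy)))
            best = max(best, dev_l)
        if new_hi < hi:
            seg = slice(new_hi + 1, hi + 1)
            dev_r = float(np.max(np.interp(xu[seg], lx, ly) - left[seg]))
            best = max(best, dev_r)

        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi

    return best / (2.0 * n)


def dip_statistic_lp(values, gap_grid: int = 48) -> float:
    """Exact dip by linear programming; independent of :func:`dip_statistic`.

    For every candidate mode position (each distinct data point, plus a grid
    of positions inside every inter-point gap) the minimal band half-width d
    admitting a monotone CDF that is chord-convex left of the mode and
    chord-concave right of it — with the CDF's left limit at the mode as an
    explicit extra variable, so the jump permitted at the mode is modelled —
    is found with an LP.  The dip is the minimum over mode positions.
    """
    from scipy.optimize import linprog

    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("dip statistic requires at least 2 observations")
    if x[0] == x[-1]:
        return 0.0

    xu, first = np.unique(x, return_index=True)
    m = xu.size
    left = first / n
    right = np.append(first[1:], n) / n

    def solve(xl, lo_l, hi_l, xr, lo_r, hi_r):
        """Min d for: values v_i at points (xl, then xr); chord-convex over the
        xl block, chord-concave over the xr block, monotone overall; bands
        lo - d <= v <= hi + d."""
        xs = np.concatenate([xl, xr])
        lo_b = np.concatenate([lo_l, lo_r])
        hi_b = np.concatenate([hi_l, hi_r])
        p = xs.size
        kL = xl.size
        c = np.zeros(p + 1)
        c[-1] = 1.0
        rows, rhs = [], []
        for i in range(p):
            r = np.zeros(p + 1); r[i] = 1.0; r[-1] = -1.0
            rows.append(r); rhs.append(hi_b[i])
            r = np.zeros(p + 1); r[i] = -1.0; r[-1] = -1.0
            rows.append(r); rhs.append(-lo_b[i])
        for i in range(p - 1):
            r = np.zeros(p + 1); r[i] = 1.0; r[i + 1] = -1.0
            rows.append(r); rhs.append(0.0)
        # chord convexity within the left block
        for i in range(1, kL - 1):
            dx0 = xs[i] - xs[i - 1]
            dx1 = xs[i + 1] - xs[i]
            r = np.zeros(p + 1)
            r[i - 1] = -dx1; r[i] = dx1 + dx0; r[i + 1] = -dx0
            rows.append(r); rhs.append(0.0)
        # chord concavity within the right block
        for i in range(kL + 1, p - 1):
            dx0 = xs[i] - xs[i - 1]
            dx1 = xs[i + 1] - xs[i]
            r = np.zeros(p + 1)
            r[i - 1] = dx1; r[i] = -(dx1 + dx0); r[i + 1] = dx0
            rows.append(r); rhs.append(0.0)
        res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs),
                      bounds=[(0.0, 1.0)] * p + [(0.0, 0.5)], method="highs")
        return res.fun if res.status == 0 else np.inf

    best = np.inf
    # mode at data point k: left block = points 0..k-1 plus the left limit at
    # x_k (band left_k ± d); right block = points k..m-1 with the point value
    # at x_k banded right_k ± d (the jump lives at x_k).
    for k in range(m):
        xl = np.append(xu[:k], xu[k])
        lo_l = np.append(right[:k], left[k])
        hi_l = np.append(left[:k], left[k])
        xr = xu[k:]
        lo_r = right[k:]
        hi_r = np.concatenate([[right[k]], left[k + 1:]])
        best = min(best, solve(xl, lo_l, hi_l, xr, lo_r, hi_r))
    # mode interior to gap k: both pieces extend to the mode position; the
    # CDF left limit and value there are banded by the gap's F_n level.
    for k in range(m - 1):
        c_level = right[k]
        for t in np.linspace(0.0, 1.0, gap_grid + 2)[1:-1]:
            xm = xu[k] * (1 - t) + xu[k + 1] * t
            xl = np.append(xu[:k + 1], xm)
            lo_l = np.append(right[:k + 1], c_level)
            hi_l = np.append(left[:k + 1], c_level)
            xr = np.append(xm, xu[k + 1:])
            lo_r = np.append(c_level, right[k + 1:])
            hi_r = np.append(c_level, left[k + 1:])
            best = min(best, solve(xl, lo_l, hi_l, xr, lo_r, hi_r))
    return float(best)
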