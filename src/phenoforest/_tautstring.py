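"""Taut-string density estimation.

The taut string through a sup-norm tube of radius ``r`` around the
empirical CDF is the function of minimal length (equivalently, minimal
number of density modes) that stays within the tube and is pinned at both
ends.  Its derivative is a piecewise-constant density whose local maxima /
minima of the slope sequence are the modes / antimodes.

Grid convention: with sorted data ``x_0 <= ... <= x_{n-1}`` the tube gates
sit at ``t_0 = x_0``, ``t_i = (x_{i-1} + x_i)/2`` (i = 1..n-1) and
``t_n = x_{n-1}``, with empirical values ``i/n`` and pinned endpoints 0
and 1.  Every inter-gate interval contains exactly one observation and
the fitted density integrates to one exactly.

The string is computed by the classical anchor-advance construction:
scan gates keeping the interval of feasible straight-line slopes from the
current anchor; on conflict, the binding wall vertex becomes a knot and
the scan restarts there.  Knots where the slope increases are floor
contacts (density antimodes); knots where it decreases are ceiling
contacts (modes).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["taut_string_fit"]


@njit(cache=True)
def _taut_string_knots(t, lo, hi):
    """Shortest path through gates [lo_i, hi_i] at positions t_i.

    lo[0] == hi[0] and lo[-1] == hi[-1] pin the endpoints.  Returns the
    knot arrays (kx, ky) including both endpoints.
    """
    n = t.shape[0]
    kx = np.empty(n + 1, np.float64)
    ky = np.empty(n + 1, np.float64)
    nk = 0
    kx[0] = t[0]
    ky[0] = lo[0]
    nk = 1
    ai = 0  # anchor gate index
    ax = t[0]
    ay = lo[0]
    while ai < n - 1:
        smin = -np.inf
        smax = np.inf
        bmin = -1  # gate index binding the floor (sets smin)
        bmax = -1  # gate index binding the ceiling (sets smax)
        j = ai + 1
        emitted = False
        while j < n:
            dx = t[j] - ax
            slo = (lo[j] - ay) / dx
            shi = (hi[j] - ay) / dx
            if slo > smax:
                # floor demands steeper than the ceiling cap: bend at the
                # ceiling's binding vertex
                kx[nk] = t[bmax]
                ky[nk] = hi[bmax]
                nk += 1
                ai = bmax
                ax = t[bmax]
                ay = hi[bmax]
                emitted = True
                break
            if shi < smin:
                # ceiling demands flatter than the floor requires: bend at
                # the floor's binding vertex
                kx[nk] = t[bmin]
                ky[nk] = lo[bmin]
                nk += 1
                ai = bmin
                ax = t[bmin]
                ay = lo[bmin]
                emitted = True
                break
            if slo > smin:
                smin = slo
                bmin = j
            if shi < smax:
                smax = shi
                bmax = j
            j += 1
        if not emitted:
            # reached the end without conflict: straight to the endpoint
            kx[nk] = t[n - 1]
            ky[nk] = lo[n - 1]
            nk += 1
            break
    return kx[:nk], ky[:nk]


def taut_string_fit(x_sorted: np.ndarray, radius: float):
    """Fit the taut-string density to sorted data.

    Returns (knot_x, knot_y, heights) where heights[i] is the density on
    [knot_x[i], knot_x[i+1]].
    """
    x = np.asarray(x_sorted, dtype=np.float64)
    n = x.shape[0]
    if n < 2:
        raise ValueError("taut string requires at least 2 observations")
    if x[-1] <= x[0]:
        raise ValueError("degenerate sample: all values equal")
    t = np.empty(n + 1, np.float64)
    t[0] = x[0]
    t[1:n] = 0.5 * (x[:-1] + x[1:])
    t[n] = x[-1]
    # strictly increasing gate positions are required; squeeze exact
    # duplicates (possible under extreme ties) by dropping them
    keep = np.ones(n + 1, dtype=bool)
    keep[1:] = np.diff(t) > 0
    idx = np.nonzero(keep)[0]
    t = t[idx]
    f = idx / n  # empirical mass at kept gates
    f[-1] = 1.0
    lo = np.maximum(f - radius, 0.0)
    hi = np.minimum(f + radius, 1.0)
    lo[0] = hi[0] = 0.0
    lo[-1] = hi[-1] = 1.0
    kx, ky = _taut_string_knots(t, lo, hi)
    heights = np.diff(ky) / np.diff(kx)
    return kx, ky, heights
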