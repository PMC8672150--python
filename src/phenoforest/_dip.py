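"""Hartigan & Hartigan dip statistic of unimodality.

The dip of an empirical CDF ``F_n`` is the smallest sup-norm distance from
``F_n`` to the class of unimodal distribution functions (nondecreasing,
convex up to a mode, concave after it; an atom is permitted at the mode).

Computation
-----------
A unimodal G within sup-distance ``t`` of ``F_n`` must satisfy, at every
distinct data value ``x_j``, ``G(x_j) in [F_j - t, F_{j-1} + t]`` where
``F_j = F_n(x_j)`` and ``F_{j-1}`` is the value just below the jump.  For a
mode in the open gap between points ``k-1`` and ``k`` the fit splits into a
convex band problem on the prefix and a concave one on the suffix, joined
at a free mode vertex ``(m, y)``.  The minimal deviation of each side
equals half the largest gap between its lower bounds and the greatest
convex minorant (least concave majorant) of its upper (lower) bounds.  The
junction is feasible iff some ``m`` in the gap admits a ``y`` above every
convex extrapolation line from the prefix and below every concave
extrapolation line from the suffix; the margin between the two envelopes
is concave in ``m`` and is maximised by ternary search.  Mode atoms at a
data point relax one band constraint per side and join at that point.

Prefix deviations are nondecreasing in the split index and suffix
deviations nonincreasing, so their maximum is valley-shaped; the minimum
over splits is found by expanding outward from the valley bottom in
ascending order of that lower bound.  A split whose junction binds is
either discarded (junction infeasible at the incumbent level) or re-solved
for its exact level by bisection.  The result is exact up to the bisection
tolerance (~1e-9) and is validated against a linear-programming oracle
solving the defining minimax problem directly (see tests).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dip_statistic", "dip_statistic_upper", "dip_quick_upper",
           "dip_bounds", "dip_cheap_upper", "dip_cheap_lower"]


# ---------------------------------------------------------------------------
# one-sided band deviations (values are 2t: twice the sup-deviation)

@njit(cache=True)
def _prefix_convex_dev(x, flo, fhi, k, atom):
    """Min 2t for a convex fit on points 0..k-1.

    Band at j is [flo[j] - t, fhi[j] + t]; returns max_j (flo[j] - gcm(x_j))
    with gcm the greatest convex minorant of (x_j, fhi[j]).  With ``atom``,
    point k-1 is the left limit of a jump at the mode and its lower check
    uses fhi[k-1] instead of flo[k-1].
    """
    if k <= 0:
        return 0.0
    hull = np.empty(k, np.int64)
    m = 0
    for j in range(k):
        while m >= 2:
            a = hull[m - 2]
            b = hull[m - 1]
            if (fhi[b] - fhi[a]) * (x[j] - x[a]) >= (fhi[j] - fhi[a]) * (
                x[b] - x[a]
            ):
                m -= 1
            else:
                break
        hull[m] = j
        m += 1
    dev = 0.0
    seg = 0
    for j in range(k):
        while seg < m - 1 and x[hull[seg + 1]] < x[j]:
            seg += 1
        a = hull[seg]
        if seg < m - 1:
            b = hull[seg + 1]
            gy = fhi[a] + (fhi[b] - fhi[a]) * (x[j] - x[a]) / (x[b] - x[a])
        else:
            gy = fhi[a]
        lo = fhi[j] if (atom and j == k - 1) else flo[j]
        d = lo - gy
        if d > dev:
            dev = d
    return dev


@njit(cache=True)
def _suffix_concave_dev(x, flo, fhi, k, atom):
    """Min 2t for a concave fit on points k..m-1 (mirror of the prefix)."""
    mtot = x.shape[0]
    if k >= mtot:
        return 0.0
    hull = np.empty(mtot - k, np.int64)
    m = 0
    for j in range(k, mtot):
        while m >= 2:
            a = hull[m - 2]
            b = hull[m - 1]
            if (flo[b] - flo[a]) * (x[j] - x[a]) <= (flo[j] - flo[a]) * (
                x[b] - x[a]
            ):
                m -= 1
            else:
                break
        hull[m] = j
        m += 1
    dev = 0.0
    seg = 0
    for j in range(k, mtot):
        while seg < m - 1 and x[hull[seg + 1]] < x[j]:
            seg += 1
        a = hull[seg]
        if seg < m - 1:
            b = hull[seg + 1]
            gy = flo[a] + (flo[b] - flo[a]) * (x[j] - x[a]) / (x[b] - x[a])
        else:
            gy = flo[a]
        hi = flo[j] if (atom and j == k) else fhi[j]
        d = gy - hi
        if d > dev:
            dev = d
    return dev


# ---------------------------------------------------------------------------
# junction envelopes
#
# For the prefix, every point j contributes a line  a_j + s_j (m - x_j)
# that lower-bounds any convex continuation at position m >= x_j, where
# a_j is its lower band value and s_j the steepest slope forced through it
# by an earlier upper band point (clipped at 0).  The mode vertex must lie
# above all of them.  The suffix is the mirror image.

@njit(cache=True)
def _conv_env(x, flo, fhi, k, atom, t, anc, slp):
    """Fill lower-envelope lines for a convex prefix 0..k-1 at level t."""
    hull = np.empty(k, np.int64)
    m = 0
    ptr = 0
    for j in range(k):
        loj = (fhi[j] if (atom and j == k - 1) else flo[j]) - t
        anc[j] = loj
        s = 0.0
        if m >= 1:
            # slope-to-query is unimodal along the hull and the maximiser
            # moves right as queries advance right and up; walk a pointer
            # and verify local optimality (full rescan on the rare miss)
            if ptr >= m:
                ptr = m - 1
            while (
                ptr + 1 < m
                and (loj - (fhi[hull[ptr + 1]] + t)) / (x[j] - x[hull[ptr + 1]])
                >= (loj - (fhi[hull[ptr]] + t)) / (x[j] - x[hull[ptr]])
            ):
                ptr += 1
            si = (loj - (fhi[hull[ptr]] + t)) / (x[j] - x[hull[ptr]])
            if ptr > 0 and (loj - (fhi[hull[ptr - 1]] + t)) / (
                x[j] - x[hull[ptr - 1]]
            ) > si:
                si = -np.inf
                for ii in range(m):
                    sii = (loj - (fhi[hull[ii]] + t)) / (x[j] - x[hull[ii]])
                    if sii > si:
                        si = sii
                        ptr = ii
            if si > s:
                s = si
        slp[j] = s
        while m >= 2:
            a = hull[m - 2]
            b = hull[m - 1]
            if (fhi[b] - fhi[a]) * (x[j] - x[a]) >= (fhi[j] - fhi[a]) * (
                x[b] - x[a]
            ):
                m -= 1
            else:
                break
        hull[m] = j
        m += 1


@njit(cache=True)
def _env_build(x, anc, slp, cnt, env_s, env_b, env_x):
    """Upper envelope of the lines anc[j] + slp[j] * (pos - x[j]).

    Writes slopes/intercepts/left-breakpoints into env_s/env_b/env_x and
    returns the number of envelope pieces (hull-trick construction).
    """
    order = np.argsort(slp[:cnt], kind="mergesort")
    m = 0
    for oi in range(cnt):
        j = order[oi]
        s = slp[j]
        b = anc[j] - s * x[j]
        if m > 0 and s == env_s[m - 1]:
            if b <= env_b[m - 1]:
                continue
            m -= 1
        while m >= 1:
            # intersection of new line with envelope top
            xi = (env_b[m - 1] - b) / (s - env_s[m - 1])
            if m >= 2 and xi <= env_x[m - 1]:
                m -= 1
            else:
                env_x[m] = xi
                break
        if m == 0:
            env_x[0] = -np.inf
        env_s[m] = s
        env_b[m] = b
        m += 1
    return m


@njit(cache=True)
def _env_eval(env_s, env_b, env_x, m, pos):
    lo = 0
    hi = m - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if env_x[mid] <= pos:
            lo = mid
        else:
            hi = mid - 1
    return env_s[lo] * pos + env_b[lo]


@njit(cache=True)
def _junction_feasible(
    x, flo, fhi, k, atom, t, anc_l, slp_l, anc_r, slp_r, xr, flor, fhir,
    es_l, eb_l, ex_l, es_r, eb_r, ex_r,
):
    """Can a convex prefix and concave suffix be joined at level t?

    The suffix is handled by reflection: H(u) = 1 - G(-u) turns the concave
    suffix into a convex prefix with bands [1 - fhi, 1 - flo].  The mode
    vertex must lie above the prefix line envelope and below the reflected
    suffix envelope; the margin is concave and piecewise linear in the
    mode position, so a ternary search over the gap is exact to floating
    precision.
    """
    mtot = x.shape[0]
    kp = k + 1 if atom else k
    if kp <= 0 or k >= mtot:
        return True
    _conv_env(x, flo, fhi, kp, atom, t, anc_l, slp_l)
    nr = mtot - k
    for i in range(nr):
        j = mtot - 1 - i
        xr[i] = -x[j]
        flor[i] = 1.0 - fhi[j]
        fhir[i] = 1.0 - flo[j]
    _conv_env(xr, flor, fhir, nr, atom, t, anc_r, slp_r)
    ml = _env_build(x, anc_l, slp_l, kp, es_l, eb_l, ex_l)
    mr = _env_build(xr, anc_r, slp_r, nr, es_r, eb_r, ex_r)
    if atom:
        pos = x[k]
        h = (
            1.0
            - _env_eval(es_r, eb_r, ex_r, mr, -pos)
            - _env_eval(es_l, eb_l, ex_l, ml, pos)
        )
        return h >= -1e-12
    xa = x[k - 1]
    xb = x[k]
    ha = (
        1.0
        - _env_eval(es_r, eb_r, ex_r, mr, -xa)
        - _env_eval(es_l, eb_l, ex_l, ml, xa)
    )
    if ha >= -1e-12:
        return True
    hb = (
        1.0
        - _env_eval(es_r, eb_r, ex_r, mr, -xb)
        - _env_eval(es_l, eb_l, ex_l, ml, xb)
    )
    if hb >= -1e-12:
        return True
    for _ in range(200):
        m1 = xa + (xb - xa) / 3.0
        m2 = xb - (xb - xa) / 3.0
        h1 = (
            1.0
            - _env_eval(es_r, eb_r, ex_r, mr, -m1)
            - _env_eval(es_l, eb_l, ex_l, ml, m1)
        )
        h2 = (
            1.0
            - _env_eval(es_r, eb_r, ex_r, mr, -m2)
            - _env_eval(es_l, eb_l, ex_l, ml, m2)
        )
        if h1 >= -1e-12 or h2 >= -1e-12:
            return True
        if h1 < h2:
            xa = m1
        else:
            xb = m2
        if xb - xa < 1e-16 * (x[mtot - 1] - x[0] + 1.0):
            break
    return False


@njit(cache=True)
def _lower_bound(x, flo, fhi, k, atom):
    if atom:
        a = _prefix_convex_dev(x, flo, fhi, k + 1, True)
        b = _suffix_concave_dev(x, flo, fhi, k, True)
    else:
        a = _prefix_convex_dev(x, flo, fhi, k, False)
        b = _suffix_concave_dev(x, flo, fhi, k, False)
    return a if a > b else b


@njit(cache=True)
def _split_value(
    x, flo, fhi, k, atom, best, anc_l, slp_l, anc_r, slp_r, xr, flor, fhir,
    es_l, eb_l, ex_l, es_r, eb_r, ex_r,
):
    """Exact minimal 2t for this split, or any value >= best if the split
    cannot beat the incumbent."""
    lb = _lower_bound(x, flo, fhi, k, atom)
    if lb >= best:
        return lb
    if _junction_feasible(
        x, flo, fhi, k, atom, 0.5 * lb, anc_l, slp_l, anc_r, slp_r, xr, flor,
        fhir, es_l, eb_l, ex_l, es_r, eb_r, ex_r,
    ):
        return lb
    # junction binds; unless this split can improve the incumbent by more
    # than the absolute tolerance, skip the bisection
    if not _junction_feasible(
        x, flo, fhi, k, atom, 0.5 * (best - 1e-9), anc_l, slp_l, anc_r,
        slp_r, xr, flor, fhir, es_l, eb_l, ex_l, es_r, eb_r, ex_r,
    ):
        return best
    lo_t = 0.5 * lb
    hi_t = 0.5 * best
    for _ in range(60):
        mid = 0.5 * (lo_t + hi_t)
        if _junction_feasible(
            x, flo, fhi, k, atom, mid, anc_l, slp_l, anc_r, slp_r, xr, flor,
            fhir, es_l, eb_l, ex_l, es_r, eb_r, ex_r,
        ):
            hi_t = mid
        else:
            lo_t = mid
        if hi_t - lo_t < 2.5e-10:
            break
    return 2.0 * hi_t


# ---------------------------------------------------------------------------
# level certificates
#
# To prove that no split can beat the incumbent level, all splits in the
# deviation window are swept once at level (best - tol)/2.  The prefix
# line envelopes are maintained incrementally in a Li Chao tree keyed by
# data position (one forward pass; the suffix side is a backward pass on
# reflected coordinates).  A split is certified dead if its junction
# margin, bounded from above by the tangent lines at the two gap
# endpoints (the margin is concave), stays negative; the rare uncertified
# splits are evaluated exactly.

@njit(cache=True)
def _lc_insert(xpos, tree_s, tree_b, tree_on, node, lo, hi, s, b):
    while True:
        if not tree_on[node]:
            tree_s[node] = s
            tree_b[node] = b
            tree_on[node] = True
            return
        mid = (lo + hi) // 2
        xm = xpos[mid]
        new_mid = s * xm + b
        cur_mid = tree_s[node] * xm + tree_b[node]
        if new_mid > cur_mid:
            ts = tree_s[node]
            tb = tree_b[node]
            tree_s[node] = s
            tree_b[node] = b
            s = ts
            b = tb
        if lo == hi:
            return
        xl = xpos[lo]
        if s * xl + b > tree_s[node] * xl + tree_b[node]:
            node = 2 * node
            hi = mid
        else:
            xh = xpos[hi]
            if s * xh + b > tree_s[node] * xh + tree_b[node]:
                node = 2 * node + 1
                lo = mid + 1
            else:
                return


@njit(cache=True)
def _lc_query(xpos, tree_s, tree_b, tree_on, i, m):
    """Max over inserted lines at xpos[i]; returns (value, slope)."""
    node = 1
    lo = 0
    hi = m - 1
    xq = xpos[i]
    bv = -np.inf
    bs = 0.0
    while True:
        if tree_on[node]:
            v = tree_s[node] * xq + tree_b[node]
            if v > bv:
                bv = v
                bs = tree_s[node]
        if lo == hi:
            return bv, bs
        mid = (lo + hi) // 2
        if i <= mid:
            node = 2 * node
            hi = mid
        else:
            node = 2 * node + 1
            lo = mid + 1


@njit(cache=True)
def _tangent_slope(x, fhi, hull, m, ptr, xj, loj, t):
    """Steepest extrapolation slope from (xj, loj) over the upper hull."""
    s = 0.0
    if m >= 1:
        if ptr >= m:
            ptr = m - 1
        while (
            ptr + 1 < m
            and (loj - (fhi[hull[ptr + 1]] + t)) / (xj - x[hull[ptr + 1]])
            >= (loj - (fhi[hull[ptr]] + t)) / (xj - x[hull[ptr]])
        ):
            ptr += 1
        si = (loj - (fhi[hull[ptr]] + t)) / (xj - x[hull[ptr]])
        if ptr > 0 and (loj - (fhi[hull[ptr - 1]] + t)) / (
            xj - x[hull[ptr - 1]]
        ) > si:
            si = -np.inf
            for ii in range(m):
                sii = (loj - (fhi[hull[ii]] + t)) / (xj - x[hull[ii]])
                if sii > si:
                    si = sii
                    ptr = ii
        if si > s:
            s = si
    return s, ptr


@njit(cache=True)
def _cert_sweep(
    x, flo, fhi, t, tol, atom, kb, ka,
    tree_s, tree_b, tree_on,
    xr, flor, fhir, rtree_s, rtree_b, rtree_on,
    lav, las, lbv, lbs, flags,
):
    """Flag splits in [kb, ka] whose junction may be feasible at level t.

    Forward pass: incremental prefix envelope (Li Chao over positions),
    recording envelope value/slope at the gap endpoints for each split.
    Backward pass: same on reflected coordinates for the suffix side,
    combining into the concave junction margin; tangent intersection
    bounds certify non-flagged splits.
    """
    m = x.shape[0]
    nt = 4 * (m + 1)
    for i in range(nt):
        tree_on[i] = False
        rtree_on[i] = False
    w = ka - kb + 1
    for i in range(w):
        flags[i] = False
    # ---- forward (prefix) pass
    hull = np.empty(m, np.int64)
    hm = 0
    ptr = 0
    for j in range(ka + 1):
        # candidate k = j uses lines 0..j-1 (tree state before insertion)
        if j >= kb:
            i = j - kb
            if not atom:
                if j >= 1:
                    v, s = _lc_query(x, tree_s, tree_b, tree_on, j - 1, m)
                    lav[i] = v
                    las[i] = s
                if j <= m - 1:
                    v, s = _lc_query(x, tree_s, tree_b, tree_on, j, m)
                    lbv[i] = v
                    lbs[i] = s
            else:
                # atom split at j: lines 0..j-1 plus the relaxed line of
                # point j, all evaluated at x[j]
                v, s = _lc_query(x, tree_s, tree_b, tree_on, j, m)
                aj = fhi[j] - t
                sj, ptr = _tangent_slope(x, fhi, hull, hm, ptr, x[j], aj, t)
                if aj >= v:
                    v = aj
                    s = sj
                lav[i] = v
                las[i] = s
        # insert the normal line of point j and push its upper bound
        aj = (flo[j] - t)
        sj, ptr = _tangent_slope(x, fhi, hull, hm, ptr, x[j], aj, t)
        _lc_insert(x, tree_s, tree_b, tree_on, 1, 0, m - 1, sj, aj - sj * x[j])
        while hm >= 2:
            a = hull[hm - 2]
            b = hull[hm - 1]
            if (fhi[b] - fhi[a]) * (x[j] - x[a]) >= (fhi[j] - fhi[a]) * (
                x[b] - x[a]
            ):
                hm -= 1
                if ptr >= hm:
                    ptr = hm - 1 if hm > 0 else 0
            else:
                break
        hull[hm] = j
        hm += 1
    # ---- backward (suffix) pass on reflected coordinates
    for i in range(m):
        j = m - 1 - i
        xr[i] = -x[j]
        flor[i] = 1.0 - fhi[j]
        fhir[i] = 1.0 - flo[j]
    hm = 0
    ptr = 0
    for k in range(m - 1, kb - 1, -1):
        ri = m - 1 - k  # reflected index of original point k
        if atom and k <= ka:
            # atom split at k: suffix lines j>k plus relaxed line of k,
            # evaluated at reflected position xr[ri] = -x[k]
            v, s = _lc_query(xr, rtree_s, rtree_b, rtree_on, ri, m)
            ak = fhir[ri] - t
            sk, ptr = _tangent_slope(xr, fhir, hull, hm, ptr, xr[ri], ak, t)
            if ak >= v:
                v = ak
                s = sk
            i = k - kb
            h = 1.0 - v - lav[i]
            if h >= -tol:
                flags[i] = True
        # insert normal reflected line of point k
        ak = flor[ri] - t
        sk, ptr = _tangent_slope(xr, fhir, hull, hm, ptr, xr[ri], ak, t)
        _lc_insert(
            xr, rtree_s, rtree_b, rtree_on, 1, 0, m - 1, sk, ak - sk * xr[ri]
        )
        while hm >= 2:
            a = hull[hm - 2]
            b = hull[hm - 1]
            if (fhir[b] - fhir[a]) * (xr[ri] - xr[a]) >= (
                fhir[ri] - fhir[a]
            ) * (xr[b] - xr[a]):
                hm -= 1
                if ptr >= hm:
                    ptr = hm - 1 if hm > 0 else 0
            else:
                break
        hull[hm] = ri
        hm += 1
        if (not atom) and k <= ka and k >= kb:
            i = k - kb
            if k == 0 or k == m:
                flags[i] = True
                continue
            # R envelope value/slope at the two gap endpoints
            rv_a, rs_a = _lc_query(
                xr, rtree_s, rtree_b, rtree_on, m - k, m
            )  # position -x[k-1]
            rv_b, rs_b = _lc_query(
                xr, rtree_s, rtree_b, rtree_on, m - 1 - k, m
            )  # position -x[k]
            ha = 1.0 - rv_a - lav[i]
            hb = 1.0 - rv_b - lbv[i]
            if ha >= -tol or hb >= -tol:
                flags[i] = True
                continue
            da = rs_a - las[i]
            db = rs_b - lbs[i]
            if da <= 0.0 or db >= 0.0:
                continue
            xa = x[k - 1]
            xb = x[k]
            xi = (hb - db * xb - ha + da * xa) / (da - db)
            u = ha + da * (xi - xa)
            if u >= -tol:
                flags[i] = True


@njit(cache=True)
def _window_edge(x, flo, fhi, atom, lim, prefix_side):
    """Largest k with prefix deviation <= lim (or smallest k with suffix
    deviation <= lim), using monotonicity of the one-sided deviations."""
    m = x.shape[0]
    kmax = m - 1 if atom else m
    if prefix_side:
        lo = 0
        hi = kmax
        # A is nondecreasing: find largest k with A(k) <= lim
        if atom:
            if _prefix_convex_dev(x, flo, fhi, 1, True) > lim:
                return -1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if atom:
                a = _prefix_convex_dev(x, flo, fhi, mid + 1, True)
            else:
                a = _prefix_convex_dev(x, flo, fhi, mid, False)
            if a <= lim:
                lo = mid
            else:
                hi = mid - 1
        if atom:
            a = _prefix_convex_dev(x, flo, fhi, lo + 1, True)
        else:
            a = _prefix_convex_dev(x, flo, fhi, lo, False)
        return lo if a <= lim else -1
    lo = 0
    hi = kmax
    # B is nonincreasing: find smallest k with B(k) <= lim
    while lo < hi:
        mid = (lo + hi) // 2
        b = _suffix_concave_dev(x, flo, fhi, mid, atom)
        if b <= lim:
            hi = mid
        else:
            lo = mid + 1
    b = _suffix_concave_dev(x, flo, fhi, lo, atom)
    return lo if b <= lim else kmax + 1


@njit(cache=True)
def _valley_bottom(x, flo, fhi, atom):
    """Split index minimising the valley-shaped lower bound."""
    m = x.shape[0]
    if atom:
        klo, khi = 0, m - 1
    else:
        klo, khi = 0, m
    while khi - klo > 1:
        k = (klo + khi) // 2
        if atom:
            a = _prefix_convex_dev(x, flo, fhi, k + 1, True)
            b = _suffix_concave_dev(x, flo, fhi, k, True)
        else:
            a = _prefix_convex_dev(x, flo, fhi, k, False)
            b = _suffix_concave_dev(x, flo, fhi, k, False)
        if a - b >= 0.0:
            khi = k
        else:
            klo = k
    ba = _lower_bound(x, flo, fhi, klo, atom)
    bb = _lower_bound(x, flo, fhi, khi, atom)
    return klo if ba <= bb else khi


@njit(cache=True)
def _dip_distinct(x, counts, n):
    m = x.shape[0]
    if m == 1:
        return 0.5 * counts[0] / n
    flo = np.empty(m, np.float64)
    fhi = np.empty(m, np.float64)
    c = 0.0
    for j in range(m):
        fhi[j] = c / n
        c += counts[j]
        flo[j] = c / n
    anc_l = np.empty(m + 1, np.float64)
    slp_l = np.empty(m + 1, np.float64)
    anc_r = np.empty(m + 1, np.float64)
    slp_r = np.empty(m + 1, np.float64)
    xr = np.empty(m + 1, np.float64)
    flor = np.empty(m + 1, np.float64)
    fhir = np.empty(m + 1, np.float64)
    es_l = np.empty(m + 1, np.float64)
    eb_l = np.empty(m + 1, np.float64)
    ex_l = np.empty(m + 1, np.float64)
    es_r = np.empty(m + 1, np.float64)
    eb_r = np.empty(m + 1, np.float64)
    ex_r = np.empty(m + 1, np.float64)
    tree_s = np.empty(4 * (m + 1), np.float64)
    tree_b = np.empty(4 * (m + 1), np.float64)
    tree_on = np.zeros(4 * (m + 1), np.bool_)
    rtree_s = np.empty(4 * (m + 1), np.float64)
    rtree_b = np.empty(4 * (m + 1), np.float64)
    rtree_on = np.zeros(4 * (m + 1), np.bool_)
    lav = np.empty(m + 2, np.float64)
    las = np.empty(m + 2, np.float64)
    lbv = np.empty(m + 2, np.float64)
    lbs = np.empty(m + 2, np.float64)
    flags = np.zeros(m + 2, np.bool_)
    TOL = 1e-8
    # seed the incumbent with the cheap constructive upper bound, then
    # refine with the exact valley-bottom splits of both families
    best = 2.0 * _dip_quick_ub(x, counts, n)
    for atom_flag in range(2):
        atom = atom_flag == 1
        k0 = _valley_bottom(x, flo, fhi, atom)
        v0 = _split_value(
            x, flo, fhi, k0, atom, best, anc_l, slp_l, anc_r, slp_r, xr,
            flor, fhir, es_l, eb_l, ex_l, es_r, eb_r, ex_r,
        )
        if v0 < best:
            best = v0
    # certificate rounds: flag the splits that might beat the incumbent
    # at level best - TOL, evaluate them exactly, repeat until none do
    for _round in range(60):
        improved = False
        lim = best - TOL
        for atom_flag in range(2):
            atom = atom_flag == 1
            kmax = m - 1 if atom else m
            ka = _window_edge(x, flo, fhi, atom, lim, True)
            kb = _window_edge(x, flo, fhi, atom, lim, False)
            if (not atom) and ka == m:
                v = _split_value(
                    x, flo, fhi, m, False, best, anc_l, slp_l, anc_r, slp_r,
                    xr, flor, fhir, es_l, eb_l, ex_l, es_r, eb_r, ex_r,
                )
                if v < best:
                    best = v
                    improved = True
                ka = m - 1
            if ka < 0 or kb > kmax or kb > ka:
                continue
            _cert_sweep(
                x, flo, fhi, 0.5 * lim, 1e-12, atom, kb, ka,
                tree_s, tree_b, tree_on,
                xr, flor, fhir, rtree_s, rtree_b, rtree_on,
                lav, las, lbv, lbs, flags,
            )
            # evaluate flagged splits from the window middle outward; a
            # sizeable improvement restarts the certificate at the lower
            # level, which typically empties the flag set
            w = ka - kb + 1
            mid = w // 2
            big_drop = False
            for step in range(w):
                off = (step + 1) // 2
                i = mid + off if step % 2 == 0 else mid - off - 1
                if i < 0 or i >= w or not flags[i]:
                    continue
                k = kb + i
                v = _split_value(
                    x, flo, fhi, k, atom, best, anc_l, slp_l, anc_r,
                    slp_r, xr, flor, fhir, es_l, eb_l, ex_l, es_r,
                    eb_r, ex_r,
                )
                if v < best:
                    if best - v > 100.0 * TOL:
                        big_drop = True
                    best = v
                    improved = True
                    if big_drop:
                        break
            if big_drop:
                break
        if not improved:
            break
    return 0.5 * best


def dip_statistic(x: np.ndarray) -> float:
    """Exact dip statistic of a one-dimensional sample.

    Parameters
    ----------
    x : array-like of real values, any order; ties allowed (the dip is
        that of the empirical distribution with atoms).

    Returns
    -------
    The dip, in [1/(2n), 0.25].
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < 1:
        raise ValueError("dip requires at least one observation")
    if n == 1:
        return 0.5
    xd, counts = np.unique(x, return_counts=True)
    return float(_dip_distinct(xd, counts.astype(np.float64), float(n)))


@njit(cache=True)
def _dip_upper_distinct(x, counts, n):
    """Upper bound on the dip: exact value of the valley-bottom split of
    each family (the full minimum ranges over all splits)."""
    m = x.shape[0]
    if m == 1:
        return 0.5 * counts[0] / n
    flo = np.empty(m, np.float64)
    fhi = np.empty(m, np.float64)
    c = 0.0
    for j in range(m):
        fhi[j] = c / n
        c += counts[j]
        flo[j] = c / n
    anc_l = np.empty(m + 1, np.float64)
    slp_l = np.empty(m + 1, np.float64)
    anc_r = np.empty(m + 1, np.float64)
    slp_r = np.empty(m + 1, np.float64)
    xr = np.empty(m + 1, np.float64)
    flor = np.empty(m + 1, np.float64)
    fhir = np.empty(m + 1, np.float64)
    es_l = np.empty(m + 1, np.float64)
    eb_l = np.empty(m + 1, np.float64)
    ex_l = np.empty(m + 1, np.float64)
    es_r = np.empty(m + 1, np.float64)
    eb_r = np.empty(m + 1, np.float64)
    ex_r = np.empty(m + 1, np.float64)
    best = 1.0
    for atom_flag in range(2):
        atom = atom_flag == 1
        k0 = _valley_bottom(x, flo, fhi, atom)
        v0 = _split_value(
            x, flo, fhi, k0, atom, best, anc_l, slp_l, anc_r, slp_r, xr,
            flor, fhir, es_l, eb_l, ex_l, es_r, eb_r, ex_r,
        )
        if v0 < best:
            best = v0
    return 0.5 * best


def dip_statistic_upper(x) -> float:
    """Cheap upper bound on the dip (exact for the valley-bottom splits).

    Because p-values decrease in the statistic, a bound below a critical
    value certifies that the exact dip is also below it, which settles
    the common "not multimodal" screening outcome without the full
    search.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < 1:
        raise ValueError("dip requires at least one observation")
    if n == 1:
        return 0.5
    xd, counts = np.unique(x, return_counts=True)
    return float(_dip_upper_distinct(xd, counts.astype(np.float64), float(n)))

@njit(cache=True)
def _atom_construction_ub(x, flo, fhi, k):
    """Upper bound on the dip from an explicit unimodal fit with an atom
    at point k: shifted prefix GCM, jump, shifted suffix LCM.  The level
    is max(A', B', A' + B' - gap)/2 with gap the LCM-GCM separation at
    the atom.  Any k yields a valid bound; O(n)."""
    m = x.shape[0]
    a = _prefix_convex_dev(x, flo, fhi, k + 1, True)
    b = _suffix_concave_dev(x, flo, fhi, k, True)
    # hull values at x[k]
    # prefix GCM of (x_i, fhi_i) for i <= k evaluated at x[k]
    hull = np.empty(k + 1, np.int64)
    hm = 0
    for j in range(k + 1):
        while hm >= 2:
            p1 = hull[hm - 2]
            p2 = hull[hm - 1]
            if (fhi[p2] - fhi[p1]) * (x[j] - x[p1]) >= (
                fhi[j] - fhi[p1]
            ) * (x[p2] - x[p1]):
                hm -= 1
            else:
                break
        hull[hm] = j
        hm += 1
    gcm_k = fhi[hull[hm - 1]]
    hull2 = np.empty(m - k, np.int64)
    hm2 = 0
    for j in range(m - 1, k - 1, -1):
        while hm2 >= 2:
            p1 = hull2[hm2 - 2]
            p2 = hull2[hm2 - 1]
            if (flo[p2] - flo[p1]) * (x[j] - x[p1]) <= (
                flo[j] - flo[p1]
            ) * (x[p2] - x[p1]):
                hm2 -= 1
            else:
                break
        hull2[hm2] = j
        hm2 += 1
    lcm_k = flo[hull2[hm2 - 1]]
    gap = lcm_k - gcm_k
    v = a if a > b else b
    j2 = a + b - gap
    if j2 > v:
        v = j2
    return 0.5 * v


@njit(cache=True)
def _dip_quick_ub(x, counts, n):
    """Cheap dip upper bound: explicit atom fits at the histogram mode
    and at the valley bottom of the atom family."""
    m = x.shape[0]
    if m == 1:
        return 0.5 * counts[0] / n
    flo = np.empty(m, np.float64)
    fhi = np.empty(m, np.float64)
    c = 0.0
    for j in range(m):
        fhi[j] = c / n
        c += counts[j]
        flo[j] = c / n
    # histogram mode: densest of 24 equal-width bins, located by index
    nb = 24
    lo_x = x[0]
    width = (x[m - 1] - x[0]) / nb
    best_mass = -1.0
    k_hist = m // 2
    if width > 0:
        edge = 0
        for b in range(nb):
            hi_x = lo_x + width * (b + 1) if b < nb - 1 else x[m - 1]
            start = edge
            while edge < m and x[edge] <= hi_x:
                edge += 1
            if edge > start:
                mass = (flo[edge - 1] - fhi[start]) / (
                    (hi_x - (lo_x + width * b)) / (x[m - 1] - x[0])
                )
                if mass > best_mass:
                    best_mass = mass
                    # densest point inside the bin
                    kb = start
                    bestc = 0.0
                    for i in range(start, edge):
                        if counts[i] > bestc:
                            bestc = counts[i]
                            kb = i
                    k_hist = (start + edge - 1) // 2 if bestc <= 1.0 else kb
    ub = _atom_construction_ub(x, flo, fhi, k_hist)
    k0 = _valley_bottom(x, flo, fhi, True)
    u2 = _atom_construction_ub(x, flo, fhi, k0)
    if u2 < ub:
        ub = u2
    return ub


def dip_quick_upper(x) -> float:
    """Fast valid upper bound on the dip statistic (O(n log n))."""
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < 1:
        raise ValueError("dip requires at least one observation")
    if n == 1:
        return 0.5
    xd, counts = np.unique(x, return_counts=True)
    return float(_dip_quick_ub(xd, counts.astype(np.float64), float(n)))


@njit(cache=True)
def _dip_lb_min(x, counts, n):
    """Certified lower bound on the dip: the minimum over splits of the
    junction-free relaxation (quasi-convex per family; binary search)."""
    m = x.shape[0]
    if m == 1:
        return 0.5 * counts[0] / n
    flo = np.empty(m, np.float64)
    fhi = np.empty(m, np.float64)
    c = 0.0
    for j in range(m):
        fhi[j] = c / n
        c += counts[j]
        flo[j] = c / n
    best = 1.0
    for atom_flag in range(2):
        atom = atom_flag == 1
        k0 = _valley_bottom(x, flo, fhi, atom)
        for k in (k0 - 1, k0, k0 + 1):
            kmax = m - 1 if atom else m
            if 0 <= k <= kmax:
                v = _lower_bound(x, flo, fhi, k, atom)
                if v < best:
                    best = v
    return 0.5 * best


def dip_bounds(x) -> tuple:
    """Certified (lower, upper) bounds on the dip statistic, O(n log n)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < 1:
        raise ValueError("dip requires at least one observation")
    if n == 1:
        return 0.5, 0.5
    xd, counts = np.unique(x, return_counts=True)
    cc = counts.astype(np.float64)
    return (
        float(_dip_lb_min(xd, cc, float(n))),
        float(_dip_quick_ub(xd, cc, float(n))),
    )


@njit(cache=True)
def _cheap_ub(x, counts, n):
    """Constructive upper bound: atom fits at the histogram mode and at a
    coarse ternary optimum of the construction value."""
    m = x.shape[0]
    if m == 1:
        return 0.5 * counts[0] / n
    flo = np.empty(m, np.float64)
    fhi = np.empty(m, np.float64)
    c = 0.0
    for j in range(m):
        fhi[j] = c / n
        c += counts[j]
        flo[j] = c / n
    nb = 24
    width = (x[m - 1] - x[0]) / nb
    k_hist = m // 2
    if width > 0:
        best_mass = -1.0
        edge = 0
        lo_x = x[0]
        for b in range(nb):
            hi_x = lo_x + width * (b + 1) if b < nb - 1 else x[m - 1]
            start = edge
            while edge < m and x[edge] <= hi_x:
                edge += 1
            if edge > start:
                mass = flo[edge - 1] - fhi[start]
                if mass > best_mass:
                    best_mass = mass
                    k_hist = (start + edge - 1) // 2
    ub = _atom_construction_ub(x, flo, fhi, k_hist)
    lo_k, hi_k = 0, m - 1
    for _ in range(9):
        if hi_k - lo_k < 3:
            break
        m1 = lo_k + (hi_k - lo_k) // 3
        m2 = hi_k - (hi_k - lo_k) // 3
        v1 = _atom_construction_ub(x, flo, fhi, m1)
        v2 = _atom_construction_ub(x, flo, fhi, m2)
        if v1 < ub:
            ub = v1
        if v2 < ub:
            ub = v2
        if v1 < v2:
            hi_k = m2 - 1
        else:
            lo_k = m1 + 1
    return ub


def dip_cheap_upper(x) -> float:
    """Very fast valid upper bound on the dip statistic."""
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < 2:
        return 0.5
    xd, counts = np.unique(x, return_counts=True)
    return float(_cheap_ub(xd, counts.astype(np.float64), float(n)))


@njit(cache=True)
def _cheap_lb(x, flo, fhi):
    """Coarse-grid lower bound on 2*dip.

    For any split point b: a mode left of x_b forces a concave fit on
    the suffix, so a chord violation  chord(flo_c, flo_e)(x_d) - fhi_d
    on points b <= c < d < e costs deviation; a mode right of x_b costs
    the mirrored convex violation on the prefix.  The dip is at least
    half of  max_b min(bestL(b), bestR(b)),  evaluated on a coarse grid
    of quantile indices.
    """
    m = x.shape[0]
    ng = 25
    if m < 3:
        return 0.0
    idx = np.empty(ng, np.int64)
    for i in range(ng):
        idx[i] = (i * (m - 1)) // (ng - 1)
    best = 0.0
    for bi in range(ng):
        b = idx[bi]
        bl = 0.0
        for ei in range(bi + 1):
            e = idx[ei]
            if x[b] <= x[e]:
                continue
            for fi in range(ei + 1, bi + 1):
                f = idx[fi]
                cy = fhi[e] + (fhi[b] - fhi[e]) * (x[f] - x[e]) / (
                    x[b] - x[e]
                )
                d = flo[f] - cy
                if d > bl:
                    bl = d
        if bl <= best:
            continue
        br = 0.0
        for ci in range(bi, ng):
            c = idx[ci]
            for ei2 in range(ci + 2, ng):
                e = idx[ei2]
                if x[e] <= x[c]:
                    continue
                for di in range(ci + 1, ei2):
                    dd = idx[di]
                    cy = flo[c] + (flo[e] - flo[c]) * (x[dd] - x[c]) / (
                        x[e] - x[c]
                    )
                    d = cy - fhi[dd]
                    if d > br:
                        br = d
        v = bl if bl < br else br
        if v > best:
            best = v
    return best


def dip_cheap_lower(x) -> float:
    """Fast valid lower bound on the dip statistic."""
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < 2:
        return 0.0
    xd, counts = np.unique(x, return_counts=True)
    flo = np.cumsum(counts) / float(n)
    fhi = np.concatenate([[0.0], flo[:-1]])
    return float(0.5 * _cheap_lb(xd, flo, fhi))
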