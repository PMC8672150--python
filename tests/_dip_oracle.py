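"""Linear-programming oracle for the dip statistic (test helper).

Solves min over unimodal CDFs G of sup|F_n - G| directly: the mode is
either a vertex in a gap between consecutive distinct points (position on
a grid; value free) or an atom at a data point (left/right limits split).
Convexity/concavity are slope constraints on consecutive polyline
segments including the mode vertex.  Exact up to the mode-position grid.
"""
import numpy as np
from scipy.optimize import linprog

MGRID = 13


def dip_lp(x):
    x = np.sort(np.asarray(x, float))
    n = len(x)
    xd, counts = np.unique(x, return_counts=True)
    m = len(xd)
    F = np.cumsum(counts) / n
    Fm1 = np.concatenate([[0.0], F[:-1]])
    if m == 1:
        return 0.5
    best = np.inf

    def solve(conv, conc, band, nv, ti):
        A, b = [], []

        def row():
            return np.zeros(nv)

        for (j, lo, hi) in band:
            r = row(); r[j] = -1; r[ti] = -1; A.append(r); b.append(-lo)
            r = row(); r[j] = 1; r[ti] = -1; A.append(r); b.append(hi)
        seq = conv + (conc[1:] if conv and conc and conv[-1] == conc[0]
                      else conc)
        for (xa, ia), (xb, ib) in zip(seq[:-1], seq[1:]):
            r = row(); r[ia] = 1; r[ib] = -1; A.append(r); b.append(0.0)
        for pts, sign in ((conv, 1.0), (conc, -1.0)):
            for (xa, ia), (xb, ib), (xc, ic) in zip(pts, pts[1:], pts[2:]):
                if xb == xa or xc == xb:
                    continue
                r = row()
                r[ia] = -sign / (xb - xa)
                r[ib] = sign / (xb - xa) + sign / (xc - xb)
                r[ic] = -sign / (xc - xb)
                A.append(r); b.append(0.0)
        c = np.zeros(nv); c[ti] = 1.0
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(0, 1)] * (nv - 1) + [(0, 1)], method="highs")
        return res.fun if res.success else np.inf

    base_band = [(j, F[j], Fm1[j]) for j in range(m)]
    pts = [(xd[j], j) for j in range(m)]
    best = min(best, solve(pts, [], base_band, m + 1, m))
    best = min(best, solve([], pts, base_band, m + 1, m))
    for k in range(1, m):
        for mm in np.linspace(xd[k - 1], xd[k], MGRID)[1:-1]:
            conv = [(xd[j], j) for j in range(k)] + [(mm, m)]
            conc = [(mm, m)] + [(xd[j], j) for j in range(k, m)]
            best = min(best, solve(conv, conc, base_band, m + 2, m + 1))
    for j in range(m):
        # atom at x_j: right limit g_j centred at F_j, left limit h (the
        # extra variable) centred at Fm1_j
        band = [
            (jj, F[jj], Fm1[jj]) for jj in range(m) if jj != j
        ] + [(j, F[j], F[j]), (m, Fm1[j], Fm1[j])]
        conv = [(xd[i], i) for i in range(j)] + [(xd[j], m)]
        conc = [(xd[i], i) for i in range(j, m)]
        best = min(best, solve(conv, conc, band, m + 2, m + 1))
    return best
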