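"""Independent brute-force oracles used to cross-check the vectorized code.

Everything here is written as plain per-scalar loops straight from the
defining formulas, deliberately sharing no code with the package.
"""

import math

import numpy as np


def gip_pairloop(profiles, gamma_prime=1.0):
    """Gaussian interaction-profile kernel, one pair at a time."""
    P = [list(map(float, row)) for row in profiles]
    n = len(P)
    mean_sq = sum(sum(x * x for x in p) for p in P) / n
    gamma = gamma_prime / mean_sq
    S = [[0.0] * n for _ in range(n)]
    for a in range(n):
        for b in range(n):
            d2 = sum((x - y) ** 2 for x, y in zip(P[a], P[b]))
            S[a][b] = math.exp(-gamma * d2)
    return np.array(S)


def projection_scalar(A, MS, DS, delta=1e-30):
    """Per-scalar transliteration of the two projections and the final score."""
    nd, nm = len(A), len(A[0])
    Ap = [[1.0 if A[i][j] == 1 else delta for j in range(nm)] for i in range(nd)]
    msp = [[0.0] * nm for _ in range(nd)]
    dsp = [[0.0] * nm for _ in range(nd)]
    ncp = [[0.0] * nm for _ in range(nd)]
    for i in range(nd):
        for j in range(nm):
            row = Ap[i]
            msj = [MS[k][j] for k in range(nm)]
            msp[i][j] = sum(row[k] * msj[k] for k in range(nm)) / math.sqrt(
                sum(x * x for x in row))
            col = [Ap[k][j] for k in range(nd)]
            dsi = [DS[i][k] for k in range(nd)]
            dsp[i][j] = sum(dsi[k] * col[k] for k in range(nd)) / math.sqrt(
                sum(x * x for x in col))
            den = math.sqrt(sum(x * x for x in dsi)) + math.sqrt(
                sum(x * x for x in msj))
            ncp[i][j] = (dsp[i][j] + msp[i][j]) / den
    return np.array(msp), np.array(dsp), np.array(ncp)


def roc_threshold_enumeration(trials, n_grid=20001):
    """ROC/AUC by exhaustive sweep of a dense percentile-threshold grid.

    trials: iterable of (rank, n_candidates).  At threshold theta a candidate
    position p (1-based) is called positive when (p-1)/(n-1) <= theta.
    """
    trials = list(trials)
    pts = []
    for theta in np.linspace(0.0, 1.0, n_grid):
        tps, fps = [], []
        for rank, n in trials:
            if n <= 1:
                tps.append(1.0)
                fps.append(0.0)
                continue
            perc = (rank - 1.0) / (n - 1.0)
            called = sum(
                1 for p in range(1, n + 1) if (p - 1.0) / (n - 1.0) <= theta + 1e-12
            )
            hit = perc <= theta + 1e-12
            tps.append(1.0 if hit else 0.0)
            fps.append(max(called - (1 if hit else 0), 0) / (n - 1.0))
        pts.append((float(np.mean(fps)), float(np.mean(tps))))
    pts = sorted(set(pts))
    pts = [(0.0, 0.0)] + pts + [(1.0, 1.0)]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    auc = 0.0
    for a in range(1, len(xs)):
        auc += (xs[a] - xs[a - 1]) * (ys[a] + ys[a - 1]) / 2.0
    return pts, auc
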