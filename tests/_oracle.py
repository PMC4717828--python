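"""Independent brute-force reference implementations used only by the tests.

Everything here is deliberately written in plain Python (loops, ``math``),
with the 2x2 eigenproblem solved through the rotation-angle closed form
(theta = atan2(2*Sxy, Sxx - Syy) / 2) rather than the characteristic-vector
route the package uses, so the two code paths share no numerics.
"""

from __future__ import annotations

import math

MISSING = -9


def _canon(v, tol=1e-12):
    """Flip a 2-vector so its first nonzero component is positive."""
    lead = v[0] if abs(v[0]) > tol else v[1]
    s = 1.0 if lead >= 0 else -1.0
    return (v[0] * s, v[1] * s)


def oracle_locus_pc(xs, ys):
    """PC statistic for one locus from complete-case (x, y) pairs.

    Returns (pc, degenerate). n < 2 returns (None, None) meaning unusable.
    """
    n = len(xs)
    assert n == len(ys)
    if n < 2:
        return None, None
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    sxx = sum((x - xbar) ** 2 for x in xs) / (n - 1)
    syy = sum((y - ybar) ** 2 for y in ys) / (n - 1)
    sxy = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys)) / (n - 1)
    tr = sxx + syy
    if tr <= 1e-12:
        return 0.0, True
    disc = math.sqrt(((sxx - syy) / 2.0) ** 2 + sxy * sxy)
    lam1 = tr / 2.0 + disc
    lam2 = tr / 2.0 - disc
    theta = 0.5 * math.atan2(2.0 * sxy, sxx - syy)
    e1 = _canon((math.cos(theta), math.sin(theta)))
    e2 = _canon((-math.sin(theta), math.cos(theta)))
    zeta1 = e1[0] * xbar + e1[1] * ybar
    zeta2 = e2[0] * xbar + e2[1] * ybar
    return n * (zeta1 + zeta2) ** 2 / (lam1 + lam2), False


def oracle_locus_z2(ds):
    """Z^2 = (sum d)^2 / sum d^2 for one locus; None if no observations."""
    if len(ds) == 0:
        return None
    ssq = sum(d * d for d in ds)
    if ssq == 0:
        return 0.0
    s = sum(ds)
    return s * s / ssq


def complete_xy(M, F, C, locus):
    """Complete-case (x, y) lists at one locus from genotype count matrices."""
    xs, ys = [], []
    for i in range(len(M)):
        m, f, c = M[i][locus], F[i][locus], C[i][locus]
        if MISSING in (m, f, c):
            continue
        xs.append(2 * c - f - m)
        ys.append(m - f)
    return xs, ys


def oracle_max_pc(M, F, C):
    """(per-locus pc list with None for unusable, max, argmax)."""
    q = len(M[0])
    per = []
    for l in range(q):
        xs, ys = complete_xy(M, F, C, l)
        pc, _ = oracle_locus_pc(xs, ys)
        per.append(pc)
    usable = [(v, l) for l, v in enumerate(per) if v is not None]
    if not usable:
        return per, None, None
    best = max(v for v, _ in usable)
    arg = min(l for v, l in usable if v == best)
    return per, best, arg


def oracle_max_z2(M, F, C, channel):
    q = len(M[0])
    per = []
    for l in range(q):
        xs, ys = complete_xy(M, F, C, l)
        ds = xs if channel == "association" else ys
        per.append(oracle_locus_z2(ds))
    usable = [(v, l) for l, v in enumerate(per) if v is not None]
    if not usable:
        return per, None, None
    best = max(v for v, _ in usable)
    arg = min(l for v, l in usable if v == best)
    return per, best, arg


def oracle_flip(M, F, C, flip_x_row, flip_y_row):
    """Apply trio-level case/complement and mother/father swaps.

    Swapping case and complement replaces C by F + M - C (negating x);
    swapping the parental labels exchanges M and F (negating y). Returns
    new (M, F, C) matrices; missing cells stay missing.
    """
    n, q = len(M), len(M[0])
    M2 = [row[:] for row in M]
    F2 = [row[:] for row in F]
    C2 = [row[:] for row in C]
    for i in range(n):
        for l in range(q):
            m, f, c = M[i][l], F[i][l], C[i][l]
            if MISSING in (m, f, c):
                continue
            if flip_x_row[i]:
                C2[i][l] = F2[i][l] + M2[i][l] - C2[i][l]
            if flip_y_row[i]:
                M2[i][l], F2[i][l] = F2[i][l], M2[i][l]
    return M2, F2, C2


def oracle_permutation_pvalue(M, F, C, statistic, flip_x, flip_y):
    """Permutation p-value recomputed from scratch for a given flip matrix."""
    def stat(Ms, Fs, Cs):
        if statistic == "max_pc":
            return oracle_max_pc(Ms, Fs, Cs)[1]
        if statistic == "max_z2_assoc":
            return oracle_max_z2(Ms, Fs, Cs, "association")[1]
        if statistic == "max_z2_maternal":
            return oracle_max_z2(Ms, Fs, Cs, "maternal")[1]
        raise ValueError(statistic)

    observed = stat(M, F, C)
    bigger = 0
    B = len(flip_x)
    for b in range(B):
        M2, F2, C2 = oracle_flip(M, F, C, flip_x[b], flip_y[b])
        if stat(M2, F2, C2) > observed:
            bigger += 1
    return bigger / B, observed
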