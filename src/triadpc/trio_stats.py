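"""Per-locus and maximum test statistics for case-parent trio designs.

For a biallelic marker let ``M``, ``F``, ``C`` be the counts of a chosen
allele carried by the mother, father and affected child of a trio.  The two
difference scores

* ``X = 2C - F - M`` — the child-versus-complement transmission contrast
  (nonzero in expectation only under association), and
* ``Y = M - F`` — the mother-versus-father contrast (nonzero in expectation
  only under a maternally mediated effect, given mating symmetry),

are stacked into ``Z = (X, Y)^T``.  The per-locus PC statistic projects the
mean of ``Z`` onto the principal axes of its sample covariance ``S``:

    PC = n * (zeta_bar_1 + zeta_bar_2)^2 / (lambda_1 + lambda_2)

with ``zeta_bar_k = e_k^T Z_bar`` and ``(lambda_k, e_k)`` the eigenpairs of
``S``.  Under the joint null of no association and no maternal effect, PC is
asymptotically chi-square with one degree of freedom.  The genome-scan
statistic ``max_PC`` is the maximum of PC over the q markers; its null
distribution (which absorbs the between-marker LD) is obtained by
permutation (see :mod:`triadpc.permutation`).

The per-locus comparator ``Z^2 = (sum d)^2 / sum d^2`` (d = X for
association, d = Y for maternal effects) and its maximum ``max_Z2`` are also
provided.

All statistics are complete-case per locus: a (trio, locus) cell enters a
locus only if mother, father and child are all genotyped there, so the
per-locus sample size ``n_l`` may differ across loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MISSING",
    "TrioGenotypes",
    "DiffVectors",
    "LocusPC",
    "MaxStatResult",
    "compute_diff_vectors",
    "check_mendelian",
    "locus_pc",
    "max_pc",
    "locus_z2",
    "max_z2",
]

log = logging.getLogger(__name__)

#: Sentinel for a missing genotype in integer count matrices.
MISSING = -9

# |Sxy| below this is treated as an exact zero.  Covariances of integer
# scores are rational with denominator n(n-1), so the smallest true nonzero
# magnitude at n = 10^4 trios is ~1e-8 while float error in the sums is
# <= ~1e-12.
_COV_TOL = 1e-10


def _as_genotype_matrix(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=np.int64)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D (n_trios x n_loci)")
    ok = (a == MISSING) | ((a >= 0) & (a <= 2))
    if not ok.all():
        bad = np.unique(a[~ok])
        raise ValueError(f"{name} contains invalid genotype codes {bad!r}; "
                         f"expected 0/1/2 or MISSING ({MISSING})")
    return a


@dataclass(frozen=True)
class TrioGenotypes:
    """Allele counts for mother (M), father (F) and affected child (C).

    Each matrix is n_trios x n_loci with entries in {0, 1, 2} or
    :data:`MISSING`.
    """

    M: np.ndarray
    F: np.ndarray
    C: np.ndarray
    snp_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "M", _as_genotype_matrix(self.M, "M"))
        object.__setattr__(self, "F", _as_genotype_matrix(self.F, "F"))
        object.__setattr__(self, "C", _as_genotype_matrix(self.C, "C"))
        if self.M.shape != self.F.shape or self.M.shape != self.C.shape:
            raise ValueError("M, F, C must have identical shapes")
        if self.M.shape[0] < 1 or self.M.shape[1] < 1:
            raise ValueError("need at least one trio and one locus")
        if self.snp_ids is not None:
            ids = tuple(str(s) for s in self.snp_ids)
            if len(ids) != self.M.shape[1]:
                raise ValueError("snp_ids length must equal n_loci")
            object.__setattr__(self, "snp_ids", ids)

    @property
    def n_trios(self) -> int:
        return self.M.shape[0]

    @property
    def n_loci(self) -> int:
        return self.M.shape[1]

    @property
    def complete(self) -> np.ndarray:
        """Boolean mask of cells where all three members are genotyped."""
        return (self.M != MISSING) & (self.F != MISSING) & (self.C != MISSING)


@dataclass(frozen=True)
class DiffVectors:
    """Difference scores X = 2C - F - M and Y = M - F with completeness mask.

    X and Y are zero-filled (and meaningless) where ``complete`` is False.
    """

    X: np.ndarray
    Y: np.ndarray
    complete: np.ndarray

    @property
    def n_trios(self) -> int:
        return self.X.shape[0]

    @property
    def n_loci(self) -> int:
        return self.X.shape[1]


def compute_diff_vectors(trios: TrioGenotypes) -> DiffVectors:
    """Form the per-trio, per-locus difference scores from genotype counts."""
    w = trios.complete
    X = np.where(w, 2 * trios.C - trios.F - trios.M, 0)
    Y = np.where(w, trios.M - trios.F, 0)
    return DiffVectors(X=X, Y=Y, complete=w)


def check_mendelian(trios: TrioGenotypes) -> list[tuple[int, int]]:
    """List (trio, locus) cells where C is impossible given M and F.

    A parent with 0 copies must transmit 0, with 2 copies must transmit 1,
    and with 1 copy may transmit either, so the feasible child counts form
    the interval [min_m + min_f, max_m + max_f].
    """
    w = trios.complete
    lo = (trios.M == 2).astype(np.int64) + (trios.F == 2).astype(np.int64)
    hi = (trios.M != 0).astype(np.int64) + (trios.F != 0).astype(np.int64)
    bad = w & ((trios.C < lo) | (trios.C > hi))
    rows, cols = np.nonzero(bad)
    return list(zip(rows.tolist(), cols.tolist()))


# ---------------------------------------------------------------------------
# 2x2 eigen machinery (closed form, shared by the scalar and batched paths)
# ---------------------------------------------------------------------------

def _eig2x2(sxx, sxy, syy):
    """Eigenvalues (descending) of symmetric [[sxx, sxy], [sxy, syy]].

    Works elementwise on arrays. Returns (lam1, lam2).
    """
    tr = sxx + syy
    disc = np.hypot(0.5 * (sxx - syy), sxy)
    return 0.5 * tr + disc, 0.5 * tr - disc


def _canonical_eigvecs(sxx, sxy, syy, lam1, lam2, eigen_sign=1.0):
    """Unit eigenvectors with the sign convention "first nonzero component
    has the sign of ``eigen_sign``", elementwise over arrays.

    When |sxy| is numerically zero the eigenvectors are the coordinate axes
    (ordered by variance); otherwise e_k is proportional to
    (sxy, lam_k - sxx), whose leading component is nonzero.
    Returns (e1x, e1y, e2x, e2y).
    """
    off = np.abs(sxy) > _COV_TOL
    sgn = np.where(sxy >= 0, 1.0, -1.0)
    b1 = lam1 - sxx
    b2 = lam2 - sxx
    n1 = np.where(off, np.hypot(sxy, b1), 1.0)
    n2 = np.where(off, np.hypot(sxy, b2), 1.0)
    a = np.abs(sxy)
    e1x = np.where(off, a / n1, np.where(sxx >= syy, 1.0, 0.0))
    e1y = np.where(off, sgn * b1 / n1, np.where(sxx >= syy, 0.0, 1.0))
    e2x = np.where(off, a / n2, np.where(sxx >= syy, 0.0, 1.0))
    e2y = np.where(off, sgn * b2 / n2, np.where(sxx >= syy, 1.0, 0.0))
    s = float(eigen_sign)
    return s * e1x, s * e1y, s * e2x, s * e2y


def _masked_scores(diffs: DiffVectors):
    """Float X, Y zeroed outside the completeness mask, plus the mask."""
    w = diffs.complete
    x = np.where(w, diffs.X, 0).astype(np.float64)
    y = np.where(w, diffs.Y, 0).astype(np.float64)
    return x, y, w.astype(np.float64)


def _pc_matrix(x, y, w, sx=None, sy=None, eigen_sign=1.0):
    """PC statistic per (permutation, locus).

    Parameters
    ----------
    x, y, w : (n, q) arrays; x, y zero-filled where w == 0.
    sx, sy : (B, n) sign matrices (+-1) applying trio-level label swaps, or
        None for the identity (observed data).

    Returns
    -------
    pc : (B, q) array — NaN where n_l < 2, 0 where the locus is degenerate
        (zero total variance).
    n_l : (q,) complete-trio counts.
    """
    if sx is None:
        sx = np.ones((1, x.shape[0]))
    if sy is None:
        sy = np.ones((1, y.shape[0]))
    n_l = w.sum(axis=0)
    valid = n_l >= 2
    sum_xx = (x * x).sum(axis=0)
    sum_yy = (y * y).sum(axis=0)
    sum_x = sx @ x
    sum_y = sy @ y
    sum_xy = (sx * sy) @ (x * y)
    with np.errstate(divide="ignore", invalid="ignore"):
        n = np.where(valid, n_l, np.nan)
        xbar = sum_x / n
        ybar = sum_y / n
        sxx = (sum_xx - n * xbar * xbar) / (n - 1)
        syy = (sum_yy - n * ybar * ybar) / (n - 1)
        sxy = (sum_xy - n * xbar * ybar) / (n - 1)
    lam1, lam2 = _eig2x2(sxx, sxy, syy)
    e1x, e1y, e2x, e2y = _canonical_eigvecs(sxx, sxy, syy, lam1, lam2, eigen_sign)
    tsum = (e1x + e2x) * xbar + (e1y + e2y) * ybar
    tr = sxx + syy
    nondeg = tr > _COV_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = np.where(nondeg, n * tsum * tsum / np.where(nondeg, tr, 1.0), 0.0)
    pc = np.where(valid, pc, np.nan)
    return pc, n_l


def _z2_matrix(d, w, s=None):
    """Z^2 per (permutation, locus): (sum d)^2 / sum d^2, 0/0 -> 0."""
    if s is None:
        s = np.ones((1, d.shape[0]))
    n_l = w.sum(axis=0)
    ssq = (d * d).sum(axis=0)
    tot = s @ d
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(ssq > 0, tot * tot / np.where(ssq > 0, ssq, 1.0), 0.0)
    z2 = np.where(n_l >= 1, z2, np.nan)
    return z2, n_l


# ---------------------------------------------------------------------------
# Scalar per-locus results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusPC:
    """Per-locus PC statistic with its eigen decomposition."""

    n_complete: int
    S: np.ndarray          # 2x2 sample covariance of (x, y)
    lambda1: float
    lambda2: float
    e1: np.ndarray
    e2: np.ndarray
    zeta_bar1: float
    zeta_bar2: float
    pc: float
    degenerate: bool = False
    usable: bool = True


def locus_pc(x, y, eigen_sign: float = 1.0) -> LocusPC:
    """PC statistic for one locus from complete-case score pairs.

    ``x`` and ``y`` must contain complete trios only.  With fewer than two
    trios the locus is flagged unusable; with zero total variance it is
    flagged degenerate and PC is 0 (the locus carries no evidence).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 2:
        return LocusPC(n_complete=n, S=np.full((2, 2), np.nan),
                       lambda1=np.nan, lambda2=np.nan,
                       e1=np.full(2, np.nan), e2=np.full(2, np.nan),
                       zeta_bar1=np.nan, zeta_bar2=np.nan,
                       pc=np.nan, degenerate=False, usable=False)
    w = np.ones((n, 1))
    pc, _ = _pc_matrix(x[:, None], y[:, None], w, eigen_sign=eigen_sign)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum() / (n - 1)
    syy = ((y - ybar) ** 2).sum() / (n - 1)
    sxy = ((x - xbar) * (y - ybar)).sum() / (n - 1)
    lam1, lam2 = _eig2x2(sxx, sxy, syy)
    e1x, e1y, e2x, e2y = _canonical_eigvecs(
        np.float64(sxx), np.float64(sxy), np.float64(syy),
        np.float64(lam1), np.float64(lam2), eigen_sign)
    e1 = np.array([e1x, e1y])
    e2 = np.array([e2x, e2y])
    degenerate = (sxx + syy) <= _COV_TOL
    return LocusPC(
        n_complete=n,
        S=np.array([[sxx, sxy], [sxy, syy]]),
        lambda1=float(max(lam1, 0.0)), lambda2=float(max(lam2, 0.0)),
        e1=e1, e2=e2,
        zeta_bar1=float(e1 @ [xbar, ybar]),
        zeta_bar2=float(e2 @ [xbar, ybar]),
        pc=float(pc[0, 0]),
        degenerate=bool(degenerate),
    )


def locus_z2(d) -> float:
    """Z^2 = (sum d)^2 / sum d^2 for one locus (0/0 -> 0)."""
    d = np.asarray(d, dtype=np.float64).ravel()
    if d.size == 0:
        raise ValueError("empty score vector: locus unusable")
    ssq = float((d * d).sum())
    if ssq == 0.0:
        return 0.0
    return float(d.sum()) ** 2 / ssq


# ---------------------------------------------------------------------------
# Maximum statistics across loci
# ---------------------------------------------------------------------------

@dataclass
class MaxStatResult:
    """A max-over-loci scan statistic and, once computed, its p-value."""

    statistic: str
    per_locus: np.ndarray          # NaN at unusable loci
    n_complete: np.ndarray         # complete trios per locus
    usable: np.ndarray             # bool per locus
    max_stat: float
    argmax_locus: int
    p_value: float | None = None
    null_stats: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def _finalize_max(name: str, per: np.ndarray, n_l: np.ndarray,
                  usable: np.ndarray) -> MaxStatResult:
    if not usable.any():
        raise ValueError(f"{name}: no usable locus")
    if not usable.all():
        log.info("%s: excluding %d unusable locus/loci (insufficient "
                 "complete trios)", name, int((~usable).sum()))
    vals = np.where(usable, per, -np.inf)
    arg = int(np.argmax(vals))  # ties -> lowest index
    return MaxStatResult(
        statistic=name,
        per_locus=per,
        n_complete=n_l.astype(np.int64),
        usable=usable,
        max_stat=float(vals[arg]),
        argmax_locus=arg,
    )


def max_pc(diffs: DiffVectors, eigen_sign: float = 1.0) -> MaxStatResult:
    """max_PC = max over loci of the per-locus PC statistic.

    Each locus uses its own complete-case trio set.  Loci with fewer than
    two complete trios are excluded from the maximum; degenerate loci
    contribute PC = 0.
    """
    x, y, w = _masked_scores(diffs)
    pc, n_l = _pc_matrix(x, y, w, eigen_sign=eigen_sign)
    per = pc[0]
    usable = n_l >= 2
    return _finalize_max("max_pc", per, n_l, usable)


def max_z2(diffs: DiffVectors, channel: str = "association") -> MaxStatResult:
    """max_Z2 over loci, using d = X ("association") or d = Y ("maternal")."""
    if channel not in ("association", "maternal"):
        raise ValueError("channel must be 'association' or 'maternal'")
    x, y, w = _masked_scores(diffs)
    d = x if channel == "association" else y
    z2, n_l = _z2_matrix(d, w)
    per = z2[0]
    usable = n_l >= 1
    name = "max_z2_assoc" if channel == "association" else "max_z2_maternal"
    return _finalize_max(name, per, n_l, usable)
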