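"""Unit and property tests for the per-locus and scan statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from triadpc import (MISSING, TrioGenotypes, check_mendelian,
                     compute_diff_vectors, locus_pc, locus_z2, max_pc, max_z2)
from triadpc.trio_stats import _pc_matrix

from _oracle import oracle_locus_pc
from conftest import random_trios


@pytest.mark.parametrize("m,f,c,x,y", [
    (2, 0, 1, 0, 2),
    (1, 1, 1, 0, 0),
    (0, 0, 0, 0, 0),
    (2, 2, 2, 0, 0),
    (1, 0, 1, 1, 1),
    (0, 2, 1, 0, -2),
])
def test_diff_vector_formulas(m, f, c, x, y):
    trios = TrioGenotypes(M=[[m]], F=[[f]], C=[[c]])
    d = compute_diff_vectors(trios)
    assert d.complete[0, 0]
    assert d.X[0, 0] == x and d.Y[0, 0] == y


def test_diff_vectors_missing_cell_excluded():
    trios = TrioGenotypes(M=[[2, 1]], F=[[2, 1]], C=[[MISSING, 1]])
    d = compute_diff_vectors(trios)
    assert not d.complete[0, 0] and d.complete[0, 1]


@given(data=st.data())
@settings(max_examples=50, deadline=None)
def test_diff_vector_bounds(data):
    """X in [-4, 4] and Y in [-2, 2] wherever the trio is complete."""
    n = data.draw(st.integers(1, 10))
    q = data.draw(st.integers(1, 4))
    geno = st.sampled_from([0, 1, 2, MISSING])
    mats = [data.draw(hnp.arrays(np.int64, (n, q), elements=geno))
            for _ in range(3)]
    d = compute_diff_vectors(TrioGenotypes(M=mats[0], F=mats[1], C=mats[2]))
    assert np.all(np.abs(d.X[d.complete]) <= 4)
    assert np.all(np.abs(d.Y[d.complete]) <= 2)
    assert np.all(d.X[~d.complete] == 0)


@pytest.mark.parametrize("m,f,c,flagged", [
    (0, 0, 1, True),
    (2, 2, 2, False),
    (1, 0, 2, True),
    (0, 2, 1, False),
    (2, 0, 0, True),
    (2, 0, 1, False),
    (1, 1, 2, False),
])
def test_mendelian_check(m, f, c, flagged):
    trios = TrioGenotypes(M=[[m]], F=[[f]], C=[[c]])
    assert (len(check_mendelian(trios)) == 1) is flagged


def test_mendelian_ignores_incomplete_cells():
    trios = TrioGenotypes(M=[[0]], F=[[0]], C=[[MISSING]])
    assert check_mendelian(trios) == []


class TestLocusPC:
    def test_all_zero_is_degenerate(self):
        res = locus_pc([0, 0, 0], [0, 0, 0])
        assert res.pc == 0.0 and res.degenerate and res.usable

    def test_zero_mean_gives_zero_pc(self):
        res = locus_pc([1, -1, 1, -1], [0, 0, 0, 0])
        assert res.pc == pytest.approx(0.0, abs=1e-12)
        assert not res.degenerate

    def test_single_trio_unusable(self):
        assert not locus_pc([1], [0]).usable

    def test_ten_trio_fixture_matches_frozen_oracle_value(self):
        # value computed by the independent rotation-angle oracle
        x = [0, 2, -1, 1, 0, -2, 1, 1, 0, -1]
        y = [1, 0, -1, 2, 0, 1, -1, 0, 1, -1]
        res = locus_pc(x, y)
        assert res.pc == pytest.approx(0.0036769220662837407, abs=1e-12)
        assert res.n_complete == 10

    def test_closed_form_equivalence(self, rng):
        """pc == n * ((e1 + e2)^T zbar)^2 / (lambda1 + lambda2)."""
        for _ in range(20):
            x = rng.integers(-4, 5, 15)
            y = rng.integers(-2, 3, 15)
            res = locus_pc(x, y)
            zbar = np.array([x.mean(), y.mean()])
            expect = 15 * float((res.e1 + res.e2) @ zbar) ** 2 / (
                res.lambda1 + res.lambda2)
            assert res.pc == pytest.approx(expect, abs=1e-10)

    def test_eigen_identities(self, rng):
        """Orthonormal eigenvectors; eigenvalues sum to trace(S)."""
        for _ in range(50):
            x = rng.integers(-4, 5, 12)
            y = rng.integers(-2, 3, 12)
            res = locus_pc(x, y)
            if res.degenerate:
                continue
            assert res.lambda1 >= res.lambda2 >= 0
            assert abs(res.e1 @ res.e1 - 1) < 1e-10
            assert abs(res.e2 @ res.e2 - 1) < 1e-10
            assert abs(res.e1 @ res.e2) < 1e-10
            assert res.lambda1 + res.lambda2 == pytest.approx(
                np.trace(res.S), abs=1e-10)
            # eigenvector equations
            for lam, e in [(res.lambda1, res.e1), (res.lambda2, res.e2)]:
                assert np.allclose(res.S @ e, lam * e, atol=1e-10)

    def test_matches_numpy_eigh(self, rng):
        for _ in range(20):
            x = rng.integers(-4, 5, 30)
            y = rng.integers(-2, 3, 30)
            res = locus_pc(x, y)
            w = np.linalg.eigvalsh(res.S)
            assert res.lambda2 == pytest.approx(w[0], abs=1e-10)
            assert res.lambda1 == pytest.approx(w[1], abs=1e-10)

    def test_matches_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 25))
            x = rng.integers(-4, 5, n)
            y = rng.integers(-2, 3, n)
            pc, _ = oracle_locus_pc(list(map(int, x)), list(map(int, y)))
            assert locus_pc(x, y).pc == pytest.approx(pc, abs=1e-10)


@pytest.mark.parametrize("d,expect", [
    ([1, 1, 1], 3.0),
    ([1, -1], 0.0),
    ([2, 0, -1, 1], 4.0 / 6.0),
    ([0, 0, 0], 0.0),
])
def test_locus_z2(d, expect):
    assert locus_z2(d) == pytest.approx(expect, abs=1e-12)


def test_locus_z2_empty_raises():
    with pytest.raises(ValueError):
        locus_z2([])


class TestMaxStatistics:
    def test_single_locus_max(self, rng):
        trios = random_trios(rng, 20, 1)
        d = compute_diff_vectors(trios)
        res = max_pc(d)
        assert res.max_stat == pytest.approx(res.per_locus[0])
        assert res.argmax_locus == 0

    def test_max_and_argmax_semantics(self, rng):
        trios = random_trios(rng, 30, 4)
        d = compute_diff_vectors(trios)
        for res in (max_pc(d), max_z2(d, "association"), max_z2(d, "maternal")):
            vals = res.per_locus[res.usable]
            assert res.max_stat == pytest.approx(np.max(vals))
            assert res.per_locus[res.argmax_locus] == pytest.approx(res.max_stat)

    def test_argmax_tie_breaks_to_lowest_index(self):
        # two identical monomorphic-in-X loci give identical Z^2 = 0
        trios = TrioGenotypes(M=[[1, 1], [1, 1]], F=[[1, 1], [1, 1]],
                              C=[[1, 1], [1, 1]])
        res = max_z2(compute_diff_vectors(trios), "association")
        assert res.max_stat == 0.0 and res.argmax_locus == 0

    def test_all_zero_scores_give_zero_max(self):
        trios = TrioGenotypes(M=np.ones((5, 3), int), F=np.ones((5, 3), int),
                              C=np.ones((5, 3), int))
        d = compute_diff_vectors(trios)
        assert max_z2(d, "association").max_stat == 0.0
        assert max_pc(d).max_stat == 0.0

    def test_one_informative_locus_dominates(self):
        M = np.ones((6, 3), int)
        F = np.ones((6, 3), int)
        C = np.ones((6, 3), int)
        C[:, 1] = 2  # consistent over-transmission at locus 2
        d = compute_diff_vectors(TrioGenotypes(M=M, F=F, C=C))
        res = max_z2(d, "association")
        assert res.argmax_locus == 1 and res.max_stat == pytest.approx(6.0)

    def test_no_usable_locus_raises(self):
        trios = TrioGenotypes(M=[[1]], F=[[1]], C=[[1]])
        with pytest.raises(ValueError):
            max_pc(compute_diff_vectors(trios))

    def test_masking_one_cell_changes_only_that_locus(self, rng):
        trios = random_trios(rng, 40, 6)
        base = max_pc(compute_diff_vectors(trios))
        Mm = trios.M.copy()
        target = 3
        Mm[7, target] = MISSING
        masked = max_pc(compute_diff_vectors(
            TrioGenotypes(M=Mm, F=trios.F, C=trios.C)))
        other = np.arange(6) != target
        assert np.array_equal(base.per_locus[other], masked.per_locus[other])
        assert masked.n_complete[target] == base.n_complete[target] - 1
        assert masked.per_locus[target] != base.per_locus[target]

    def test_allele_recoding_invariance(self, rng):
        """Counting the other allele (c -> 2 - c) negates X and Y at that
        locus and leaves PC and Z^2 unchanged."""
        trios = random_trios(rng, 40, 5, missing_rate=0.1)
        flipped = TrioGenotypes(
            M=np.where(trios.M == MISSING, MISSING, 2 - trios.M),
            F=np.where(trios.F == MISSING, MISSING, 2 - trios.F),
            C=np.where(trios.C == MISSING, MISSING, 2 - trios.C))
        d0, d1 = compute_diff_vectors(trios), compute_diff_vectors(flipped)
        assert np.array_equal(d1.X, -d0.X) and np.array_equal(d1.Y, -d0.Y)
        assert max_pc(d1).per_locus == pytest.approx(
            max_pc(d0).per_locus, abs=1e-10)
        for ch in ("association", "maternal"):
            assert max_z2(d1, ch).per_locus == pytest.approx(
                max_z2(d0, ch).per_locus, abs=1e-10)


def test_batched_pc_agrees_with_scalar_path(rng):
    """The vectorized permutation kernel and locus_pc share conventions."""
    trios = random_trios(rng, 30, 8, missing_rate=0.15)
    d = compute_diff_vectors(trios)
    batched = max_pc(d).per_locus
    for l in range(8):
        w = d.complete[:, l]
        res = locus_pc(d.X[w, l], d.Y[w, l])
        if not res.usable:
            assert np.isnan(batched[l])
        else:
            assert batched[l] == pytest.approx(res.pc, abs=1e-10)


def test_pc_matrix_eigen_sign_has_no_effect_on_pc(rng):
    x = rng.integers(-4, 5, (20, 3)).astype(float)
    y = rng.integers(-2, 3, (20, 3)).astype(float)
    w = np.ones((20, 3))
    a, _ = _pc_matrix(x, y, w, eigen_sign=1.0)
    b, _ = _pc_matrix(x, y, w, eigen_sign=-1.0)
    assert np.array_equal(a, b)
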