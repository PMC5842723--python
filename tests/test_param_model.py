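"""Matrix rationality test and GOP/GEP estimation.

The closed forms are cross-checked against an independent symbolic
construction of the same expressions in sympy, lambdified and evaluated
on seeded random family statistics; matrix means are cross-checked
against biotite's canonical matrix tables.
"""

import numpy as np
import pytest
import sympy

from msaparam.family_stats import FamilyStats
from msaparam.io_formats import STANDARD_AA
from msaparam.param_model import (
    NonPositiveBoundError,
    Weights,
    check_matrix,
    estimate_gop_gep,
    gop_upper_bound,
    matrix_means,
    select_preset,
)

from conftest import toy_matrix


def _sympy_forms():
    """Independent symbolic build of the two right-hand sides."""
    m, ng, nm, saa, sab, al, be, n, lam = sympy.symbols(
        "m ng nm saa sab alpha beta n lam", positive=True
    )
    calc = (al * m - 2 * al - m) / ((1 - m) * 2 * be) * (ng / nm) + sab / be
    bound = (
        ((al * m - 2 * al - m) * (m - 1) / 2 * ng * sab + nm * (be * saa - sab))
        * n * lam / (m * (n + lam - 1) * ng)
    )
    args = (m, ng, nm, saa, sab, al, be, n, lam)
    return (
        sympy.lambdify(args, calc, "numpy"),
        sympy.lambdify(args, bound, "numpy"),
    )


CALC_ORACLE, BOUND_ORACLE = _sympy_forms()


def random_stats(rng):
    m = int(rng.integers(2, 30))
    len_min = int(rng.integers(10, 400))
    len_max = len_min + int(rng.integers(0, 120))
    iden = float(rng.uniform(0.05, 1.0))
    return FamilyStats.from_parts(m=m, len_max=len_max, len_min=len_min, iden=iden)


class TestMatrixMeans:
    def test_toy_matrix(self):
        ms = matrix_means(toy_matrix(5, -1))
        assert (ms.mean_saa, ms.mean_sab) == (5.0, -1.0)

    @pytest.mark.parametrize("name", ["BLOSUM30", "BLOSUM45", "BLOSUM62"])
    def test_against_independent_canonical_tables(self, name, request):
        import biotite.sequence as bseq
        import biotite.sequence.align as balign

        mine = matrix_means(request.getfixturevalue(name.lower()))
        ref = balign.SubstitutionMatrix(
            bseq.ProteinSequence.alphabet, bseq.ProteinSequence.alphabet, name
        )
        diag = [ref.get_score(a, a) for a in STANDARD_AA]
        off = [
            ref.get_score(a, b)
            for i, a in enumerate(STANDARD_AA)
            for b in STANDARD_AA[i + 1 :]
        ]
        assert mine.mean_saa == pytest.approx(sum(diag) / 20)
        assert mine.mean_sab == pytest.approx(sum(off) / 190)
        assert mine.mean_saa > mine.mean_sab


class TestCheckMatrix:
    def test_zero_gap_budget_reduces_to_mismatch_term(self, blosum62):
        stats = FamilyStats(m=4, len_max=10, len_min=10, iden=0.5,
                            num_match=30.0, num_gap=0)
        ms = matrix_means(blosum62)
        chk = check_matrix(stats, ms, Weights())
        assert chk.calc == pytest.approx(ms.mean_sab / 0.9)
        assert chk.passed  # mean match score clears mean mismatch / beta

    def test_matches_symbolic_oracle(self, blosum45):
        rng = np.random.default_rng(101)
        ms = matrix_means(blosum45)
        w = Weights()
        for _ in range(1000):
            stats = random_stats(rng)
            chk = check_matrix(stats, ms, w)
            expected = CALC_ORACLE(
                stats.m, stats.num_gap, stats.num_match,
                ms.mean_saa, ms.mean_sab, w.alpha, w.beta, w.n, w.lam,
            )
            assert chk.calc == pytest.approx(float(expected), rel=1e-12)
            assert chk.passed == (chk.reference >= chk.calc)

    def test_toy_matrix_unit_ratio(self):
        """diag=5/off=-1, m=4, defaults, num_gap/num_match = 1."""
        stats = FamilyStats(m=4, len_max=10, len_min=10, iden=0.5,
                            num_match=12.0, num_gap=12)
        chk = check_matrix(stats, matrix_means(toy_matrix(5, -1)), Weights())
        expected = CALC_ORACLE(4, 12, 12, 5.0, -1.0, 0.2, 0.9, 5, 3)
        assert chk.calc == pytest.approx(float(expected))
        assert chk.reference == 5.0

    def test_more_matches_pull_calc_toward_mismatch_term(self, blosum62):
        ms = matrix_means(blosum62)
        w = Weights()
        s1 = FamilyStats(m=4, len_max=100, len_min=90, iden=0.3,
                         num_match=100.0, num_gap=30)
        s2 = FamilyStats(m=4, len_max=100, len_min=90, iden=0.3,
                         num_match=200.0, num_gap=30)
        c1, c2 = check_matrix(s1, ms, w).calc, check_matrix(s2, ms, w).calc
        limit = ms.mean_sab / w.beta
        assert abs(c2 - limit) < abs(c1 - limit)

    def test_zero_identity_rejected_with_advice(self, blosum62):
        stats = FamilyStats(m=4, len_max=10, len_min=10, iden=0.0,
                            num_match=0.0, num_gap=5)
        with pytest.raises(ValueError, match="override"):
            check_matrix(stats, matrix_means(blosum62), Weights())


class TestGopUpperBound:
    def test_identical_family_toy_matrix_vs_oracle(self):
        stats = FamilyStats.from_parts(m=3, len_max=10, len_min=10, iden=1.0)
        w = Weights(lam=3, n=5, omega=0.05)
        bound = gop_upper_bound(stats, matrix_means(toy_matrix(5, -1)), w)
        expected = BOUND_ORACLE(3, stats.num_gap, stats.num_match,
                                5.0, -1.0, 0.2, 0.9, 5, 3)
        assert bound == pytest.approx(float(expected))

    def test_matches_symbolic_oracle_on_random_draws(self, blosum62):
        rng = np.random.default_rng(202)
        ms = matrix_means(blosum62)
        for _ in range(1000):
            stats = random_stats(rng)
            w = Weights(
                lam=int(rng.integers(1, 6)),
                n=int(rng.integers(1, 15)),
                omega=float(rng.uniform(0.01, 0.99)),
            )
            bound = gop_upper_bound(stats, ms, w)
            expected = BOUND_ORACLE(
                stats.m, stats.num_gap, stats.num_match,
                ms.mean_saa, ms.mean_sab, w.alpha, w.beta, w.n, w.lam,
            )
            assert bound == pytest.approx(float(expected), rel=1e-12)

    def test_increasing_beta_raises_bound(self, blosum45):
        stats = FamilyStats.from_parts(m=4, len_max=120, len_min=100, iden=0.4)
        ms = matrix_means(blosum45)
        b1 = gop_upper_bound(stats, ms, Weights(beta=0.5))
        b2 = gop_upper_bound(stats, ms, Weights(beta=0.9))
        assert b2 > b1

    def test_scaling_counts_preserves_sign(self, blosum45):
        ms = matrix_means(blosum45)
        w = Weights()
        s1 = FamilyStats(m=4, len_max=100, len_min=90, iden=0.4,
                         num_match=120.0, num_gap=30)
        s2 = FamilyStats(m=4, len_max=100, len_min=90, iden=0.4,
                         num_match=360.0, num_gap=90)
        b1 = gop_upper_bound(s1, ms, w)
        b2 = gop_upper_bound(s2, ms, w)
        assert np.sign(b1) == np.sign(b2)

    def test_zero_gap_budget_rejected(self, blosum62):
        stats = FamilyStats(m=4, len_max=10, len_min=10, iden=0.5,
                            num_match=30.0, num_gap=0)
        with pytest.raises(ValueError, match="num_gap"):
            gop_upper_bound(stats, matrix_means(blosum62), Weights())


class TestEstimateGopGep:
    def test_definitional_composition(self, blosum45):
        stats = FamilyStats.from_parts(m=4, len_max=110, len_min=100, iden=0.4)
        w = Weights(lam=3, n=5, omega=0.05)
        est = estimate_gop_gep(stats, blosum45, w)
        bound = gop_upper_bound(stats, matrix_means(blosum45), w)
        assert est.gop == pytest.approx(0.05 * bound)
        assert est.gep == pytest.approx(est.gop / 5)
        assert 0 < est.gop <= est.upper_bound

    def test_linear_in_omega(self, blosum45):
        stats = FamilyStats.from_parts(m=4, len_max=110, len_min=100, iden=0.4)
        e1 = estimate_gop_gep(stats, blosum45, Weights(omega=0.04))
        e2 = estimate_gop_gep(stats, blosum45, Weights(omega=0.08))
        assert e2.gop == pytest.approx(2 * e1.gop)
        assert e2.gep == pytest.approx(2 * e1.gep)

    def test_gep_times_n_is_gop_exactly(self, blosum62):
        rng = np.random.default_rng(77)
        for _ in range(50):
            stats = random_stats(rng)
            w = Weights(n=int(rng.integers(1, 12)),
                        omega=float(rng.uniform(0.01, 0.9)))
            try:
                est = estimate_gop_gep(stats, blosum62, w)
            except NonPositiveBoundError:
                continue
            assert est.gep * w.n == pytest.approx(est.gop, rel=1e-12)

    def test_strictly_increasing_in_omega(self, blosum45):
        stats = FamilyStats.from_parts(m=5, len_max=200, len_min=150, iden=0.3)
        gops = [
            estimate_gop_gep(stats, blosum45, Weights(omega=o)).gop
            for o in (0.01, 0.05, 0.2, 0.6, 0.95)
        ]
        assert all(x < y for x, y in zip(gops, gops[1:]))

    def test_non_positive_bound_is_error_not_clamp(self):
        # a mismatch-rewarding matrix drives the bound negative
        bad = toy_matrix(diag=-5, off=-1)
        stats = FamilyStats.from_parts(m=4, len_max=100, len_min=90, iden=0.3)
        with pytest.raises(NonPositiveBoundError, match="non-positive"):
            estimate_gop_gep(stats, bad, Weights())


class TestSelectPreset:
    @pytest.mark.parametrize(
        "m,len_max,omega,n,matrix",
        [
            (4, 80, 0.03, 5, "blosum45"),
            (4, 150, 0.05, 5, "blosum45"),
            (5, 100, 0.05, 5, "blosum45"),
            (5, 300, 0.05, 5, "blosum45"),
            (4, 301, 0.08, 10, "blosum62"),
            (14, 200, 0.02, 10, "blosum45"),
            (19, 500, 0.02, 10, "blosum45"),
            (25, 400, 0.02, 10, "blosum45"),
        ],
    )
    def test_published_classes(self, m, len_max, omega, n, matrix):
        stats = FamilyStats.from_parts(m=m, len_max=len_max,
                                       len_min=max(1, len_max - 10), iden=0.4)
        w, name, extrapolated = select_preset(stats)
        assert (w.omega, w.n, name) == (omega, n, matrix)
        assert (w.lam, w.alpha, w.beta) == (3, 0.2, 0.9)
        assert not extrapolated

    @pytest.mark.parametrize("m", [2, 3, 6, 13])
    def test_unpublished_small_m_extrapolates_and_flags(self, m):
        stats = FamilyStats.from_parts(m=m, len_max=150, len_min=140, iden=0.4)
        w, name, extrapolated = select_preset(stats)
        assert (w.omega, w.n, name) == (0.05, 5, "blosum45")
        assert extrapolated
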