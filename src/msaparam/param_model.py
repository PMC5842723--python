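"""Theory-driven choice of substitution matrix and affine gap penalties.

The model compares the sum-of-pairs score of a family before and after
alignment under a worst-case gap scenario.  Demanding that aligning can
never lower the score yields two closed forms, both driven entirely by
family statistics (m, len_min, len_max, iden) and the matrix-wide mean
match score mean(S_aa) and mean mismatch score mean(S_ab):

* a rationality condition on the substitution matrix,

      mean(S_aa) >= (alpha*m - 2*alpha - m) / ((1 - m) * 2*beta)
                    * num_gap / num_match  +  mean(S_ab) / beta,

  read as ``reference >= calc`` - a matrix failing it cannot reward
  alignment for this family at all;

* an upper bound on the gap open penalty,

      GOP <= [ (alpha*m - 2*alpha - m) * (m-1)/2 * num_gap * S_ab
               + num_match * (beta*S_aa - S_ab) ]
             * n*lambda / (m * (n + lambda - 1) * num_gap),

  from which the working estimate is GOP = omega * bound and
  GEP = GOP / n.

lambda is the assumed ratio of gap characters to gap openings per
sequence, n the fixed GOP/GEP ratio, omega in (0,1) the fraction of the
bound actually charged, and alpha/beta down-weight worst-case mismatch
and match contributions.  The preset table maps family shape (m,
len_max) to the empirically best (omega, n, matrix) combination; lambda,
alpha, beta are global constants (3, 0.2, 0.9).

Both closed forms are implemented exactly as printed above; no algebraic
rearrangement is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from .family_stats import FamilyStats
from .io_formats import STANDARD_AA, SubstitutionMatrix

#: Global weight-coefficient constants shared by every preset.
DEFAULT_LAMBDA = 3
DEFAULT_ALPHA = 0.2
DEFAULT_BETA = 0.9


@dataclass(frozen=True)
class Weights:
    """Tuning constants of the penalty model.

    lam: gap characters per gap opening (>= 1).
    n: GOP/GEP ratio (>= 1).
    omega: fraction of the GOP upper bound charged, in (0, 1).
    alpha, beta: worst-case mismatch/match down-weights.
    """

    lam: int = DEFAULT_LAMBDA
    n: int = 5
    omega: float = 0.05
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if self.lam < 1 or self.n < 1:
            raise ValueError("lam and n must be positive integers")
        if not 0.0 < self.omega < 1.0:
            raise ValueError("omega must lie strictly in (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class MatrixStats:
    """Matrix-wide mean scores: diagonal (match) and off-diagonal (mismatch)."""

    mean_saa: float
    mean_sab: float


@dataclass(frozen=True)
class MatrixCheck:
    """Outcome of the matrix-rationality test ``reference >= calc``."""

    reference: float
    calc: float
    passed: bool


@dataclass(frozen=True)
class ParamEstimate:
    """A complete, auditable parameter recommendation."""

    gop: float
    gep: float
    upper_bound: float
    matrix_name: str
    weights: Weights
    stats: FamilyStats
    extrapolated: bool = False

    def as_dict(self) -> dict:
        return {
            "gop": self.gop,
            "gep": self.gep,
            "upper_bound": self.upper_bound,
            "matrix": self.matrix_name,
            "omega": self.weights.omega,
            "n": self.weights.n,
            "lambda": self.weights.lam,
            "alpha": self.weights.alpha,
            "beta": self.weights.beta,
            "extrapolated_preset": self.extrapolated,
        }


def matrix_means(matrix: SubstitutionMatrix) -> MatrixStats:
    """Mean match and mismatch scores over the 20 standard amino acids.

    mean_saa averages the 20 diagonal entries; mean_sab the 190
    strict-upper-triangle entries.  Ambiguity codes are excluded.
    """
    diag = [matrix.score(a, a) for a in STANDARD_AA]
    off = [
        matrix.score(a, b)
        for i, a in enumerate(STANDARD_AA)
        for b in STANDARD_AA[i + 1 :]
    ]
    return MatrixStats(mean_saa=sum(diag) / len(diag), mean_sab=sum(off) / len(off))


def check_matrix(stats: FamilyStats, mstats: MatrixStats, w: Weights) -> MatrixCheck:
    """Test whether a matrix can reward alignment of this family.

    ``reference`` is mean(S_aa); ``calc`` is the right-hand side of the
    rationality inequality.  ``passed`` is reference >= calc.
    """
    if stats.num_match <= 0:
        raise ValueError(
            "num_match is zero (identity 0); supply an identity override "
            "before testing matrix rationality"
        )
    m, a, b = stats.m, w.alpha, w.beta
    calc = ((a * m - 2 * a - m) / ((1 - m) * 2 * b)) * (
        stats.num_gap / stats.num_match
    ) + mstats.mean_sab / b
    return MatrixCheck(
        reference=mstats.mean_saa, calc=calc, passed=mstats.mean_saa >= calc
    )


def gop_upper_bound(stats: FamilyStats, mstats: MatrixStats, w: Weights) -> float:
    """Largest gap open penalty under which aligning still pays.

    Evaluates the closed-form bound with S_aa, S_ab replaced by the
    matrix-wide means.  The caller decides what to do with a
    non-positive value; see :func:`estimate_gop_gep`.
    """
    if stats.num_gap <= 0:
        raise ValueError("num_gap is zero: no gaps expected, no penalty to bound")
    if stats.num_match <= 0:
        raise ValueError("num_match is zero; supply an identity override")
    m, a, b = stats.m, w.alpha, w.beta
    saa, sab = mstats.mean_saa, mstats.mean_sab
    numerator = (a * m - 2 * a - m) * ((m - 1) / 2) * stats.num_gap * sab + (
        stats.num_match * (b * saa - sab)
    )
    return numerator * (w.n * w.lam) / (m * (w.n + w.lam - 1) * stats.num_gap)


class NonPositiveBoundError(ValueError):
    """The penalty formula yielded a non-positive GOP for these inputs."""

    def __init__(self, bound: float, stats: FamilyStats, mstats: MatrixStats):
        self.bound = bound
        super().__init__(
            f"formula yields non-positive GOP (upper bound {bound:.4f}) for "
            f"m={stats.m}, len=[{stats.len_min},{stats.len_max}], "
            f"iden={stats.iden:.3f}, mean_saa={mstats.mean_saa:.3f}, "
            f"mean_sab={mstats.mean_sab:.3f}; the family statistics are "
            "degenerate - consider an identity override or default penalties"
        )


def estimate_gop_gep(
    stats: FamilyStats,
    matrix: SubstitutionMatrix,
    w: Weights,
    matrix_name: str | None = None,
    extrapolated: bool = False,
) -> ParamEstimate:
    """Estimate (GOP, GEP) for a family: GOP = omega * bound, GEP = GOP / n.

    Raises :class:`NonPositiveBoundError` rather than clamping when the
    bound is not positive.
    """
    mstats = matrix_means(matrix)
    bound = gop_upper_bound(stats, mstats, w)
    if bound <= 0:
        raise NonPositiveBoundError(bound, stats, mstats)
    gop = w.omega * bound
    return ParamEstimate(
        gop=gop,
        gep=gop / w.n,
        upper_bound=bound,
        matrix_name=matrix_name or matrix.name,
        weights=w,
        stats=stats,
        extrapolated=extrapolated,
    )


#: Preset rows: (m condition, len_max condition) -> (omega, n, matrix).
#: Families with 2 <= m <= 13 use the small-family rows (the published
#: table has no 6-13 class; the nearest class is applied and flagged).
def select_preset(stats: FamilyStats) -> tuple[Weights, str, bool]:
    """Pick the empirically optimal (omega, n, matrix) for a family shape.

    Returns (weights, matrix_name, extrapolated); ``extrapolated`` marks
    family shapes outside the published classes, resolved to the nearest
    one.
    """
    m, length = stats.m, stats.len_max
    extrapolated = False
    if m <= 13:
        if not 4 <= m <= 5:
            extrapolated = True
        if length < 100:
            omega, n, name = 0.03, 5, "blosum45"
        elif length <= 300:
            omega, n, name = 0.05, 5, "blosum45"
        else:
            omega, n, name = 0.08, 10, "blosum62"
    elif m <= 19:
        omega, n, name = 0.02, 10, "blosum45"
    else:
        omega, n, name = 0.02, 10, "blosum45"
    w = Weights(
        lam=DEFAULT_LAMBDA, n=n, omega=omega, alpha=DEFAULT_ALPHA, beta=DEFAULT_BETA
    )
    return w, name, extrapolated


def auto_estimate(stats: FamilyStats) -> ParamEstimate:
    """Preset selection followed by penalty estimation, in one step."""
    from .io_formats import load_matrix

    w, name, extrapolated = select_preset(stats)
    return estimate_gop_gep(
        stats, load_matrix(name), w, matrix_name=name, extrapolated=extrapolated
    )
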