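"""Sum-of-pairs objective and the SPS benchmark metric.

The SP score of an alignment is the total pairwise residue score over
all columns minus the total affine gap penalty,

    score = sum(Residue) - sum(penalty),
    sum(penalty) = N_GOP * GOP + N_GEP * GEP,

where every maximal gap run contributes one opening and (length - 1)
extensions.  Residue-gap and gap-gap column pairs score zero; terminal
runs are penalized like internal ones.

SPS compares a test alignment against a curated reference: of all
residue pairs the reference places in the same column, the fraction the
test alignment also places together.  1.0 means perfect agreement on
reference-aligned pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .io_formats import GAP, Alignment, SubstitutionMatrix


@dataclass(frozen=True)
class GapDecomposition:
    """Counts of gap openings and extensions across all rows."""

    n_gop: int
    n_gep: int

    @property
    def total_gaps(self) -> int:
        return self.n_gop + self.n_gep


@dataclass(frozen=True)
class SPResult:
    residue_total: float
    penalty_total: float

    @property
    def score(self) -> float:
        return self.residue_total - self.penalty_total


def residue_cost(a: str, b: str, matrix: SubstitutionMatrix) -> float:
    """Score of one column pair: matrix score for two residues, zero if
    either symbol is a gap."""
    if a == GAP or b == GAP:
        return 0.0
    return float(matrix.score(a, b))


def count_gaps(aln: Alignment) -> GapDecomposition:
    """Decompose the alignment's gaps into openings and extensions.

    Each maximal run of '-' in a row contributes one opening and
    (run length - 1) extensions; n_gop + n_gep equals the total number
    of gap characters.
    """
    n_gop = n_gep = 0
    for row in aln.rows:
        in_run = False
        for ch in row:
            if ch == GAP:
                if in_run:
                    n_gep += 1
                else:
                    n_gop += 1
                    in_run = True
            else:
                in_run = False
    return GapDecomposition(n_gop=n_gop, n_gep=n_gep)


def sp_score(
    aln: Alignment,
    matrix: SubstitutionMatrix,
    gop: float,
    gep: float,
) -> SPResult:
    """Sum-of-pairs score of an alignment under a matrix and affine penalties."""
    if gop <= 0 or gep < 0:
        raise ValueError("need gop > 0 and gep >= 0")
    from .aligner import _matrix_array

    idx, arr = _matrix_array(matrix)
    gap_code = len(idx)
    # pad the matrix with a zero-scoring gap row/column, then sum over
    # all column pairs with one matrix product per row pair
    padded = np.zeros((gap_code + 1, gap_code + 1))
    padded[:gap_code, :gap_code] = arr
    coded = [
        np.array([gap_code if c == GAP else idx[c] for c in row], dtype=np.intp)
        for row in aln.rows
    ]
    residue_total = 0.0
    for ra, rb in itertools.combinations(coded, 2):
        residue_total += float(padded[ra, rb].sum())
    gaps = count_gaps(aln)
    penalty_total = gaps.n_gop * gop + gaps.n_gep * gep
    return SPResult(residue_total=residue_total, penalty_total=penalty_total)


def _aligned_pairs(aln: Alignment) -> set[tuple[int, int, int, int]]:
    """Set of (row_i, residue_index_i, row_j, residue_index_j) pairs the
    alignment places in the same column, i < j, indices counted over the
    ungapped sequences."""
    k = len(aln)
    counters = [0] * k
    pairs: set[tuple[int, int, int, int]] = set()
    rows = aln.rows
    for col in range(aln.length):
        present = [
            (i, counters[i]) for i in range(k) if rows[i][col] != GAP
        ]
        for (i, pi), (j, pj) in itertools.combinations(present, 2):
            pairs.add((i, pi, j, pj))
        for i, _ in present:
            counters[i] += 1
    return pairs


def sps(test: Alignment, ref: Alignment) -> float:
    """Reference-denominated pair recall in [0, 1].

    Both alignments must cover the same sequences (same ids, same
    residues once gaps are stripped); rows are matched by id.
    """
    if sorted(test.ids) != sorted(ref.ids):
        raise ValueError("alignments cover different sequence ids")
    test_lookup = dict(test.records)
    reordered = tuple((sid, test_lookup[sid]) for sid, _ in ref.records)
    test = Alignment(reordered)
    for (sid, trow), (_, rrow) in zip(test.records, ref.records):
        if trow.replace(GAP, "") != rrow.replace(GAP, ""):
            raise ValueError(f"ungapped sequence mismatch for id {sid!r}")
    ref_pairs = _aligned_pairs(ref)
    if not ref_pairs:
        raise ValueError("reference alignment aligns no residue pairs")
    test_pairs = _aligned_pairs(test)
    return len(ref_pairs & test_pairs) / len(ref_pairs)
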