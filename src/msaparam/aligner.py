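"""A small, exact progressive multiple aligner.

Pairwise alignment is Gotoh's three-state affine-gap dynamic programme;
families are merged profile-to-profile along a UPGMA guide tree built on
1 - pairwise identity.  The gap model matches the objective the package
scores with: a run of R gaps costs gop + (R - 1) * gep, terminal runs
included.

The aligner is deliberately plain - no iterative refinement, no
consistency heuristics - because its job is to let estimated gap
parameters be exercised end to end, not to compete with production
aligners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import GAP, Alignment, SequenceSet, SubstitutionMatrix

_NEG = -1.0e30  # effectively -inf, but arithmetic-safe
_TOL = 1e-6


def _matrix_array(matrix: SubstitutionMatrix) -> tuple[dict[str, int], np.ndarray]:
    """Dense score array + letter index for fast lookups."""
    idx = {a: i for i, a in enumerate(matrix.alphabet)}
    arr = np.zeros((len(idx), len(idx)))
    for a, i in idx.items():
        for b, j in idx.items():
            arr[i, j] = matrix.score(a, b)
    return idx, arr


def _encode(seq: str, idx: dict[str, int]) -> np.ndarray:
    try:
        return np.array([idx[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise KeyError(f"residue {exc.args[0]!r} not covered by the matrix") from None


def _affine_dp(colscore: np.ndarray, gop: float, gep: float) -> tuple[float, str]:
    """Three-state affine DP over a precomputed column-score matrix.

    ``colscore[i, j]`` is the gain for pairing row-unit i with column-unit
    j.  Returns the optimal score and the traceback operation string over
    {'M', 'D', 'I'}: D consumes the first axis against a gap, I the second.
    """
    n, m = colscore.shape
    M = np.full((n + 1, m + 1), _NEG)
    D = np.full((n + 1, m + 1), _NEG)
    I = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if m:
        I[0, 1:] = -gop - gep * np.arange(m)
    j_idx = np.arange(m + 1)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], D[i - 1]), I[i - 1])
        M[i, 1:] = colscore[i - 1] + best_prev[:-1]
        D[i] = np.maximum(np.maximum(M[i - 1], I[i - 1]) - gop, D[i - 1] - gep)
        # I[i, j] = max_{k<j} max(M[i,k], D[i,k]) - gop - (j-1-k)*gep,
        # computed as a running maximum so the row stays vectorized.
        opener = np.maximum(M[i], D[i]) + gep * j_idx
        run = np.maximum.accumulate(opener)
        I[i, 1:] = run[:-1] - gop - gep * (j_idx[1:] - 1)
    # traceback preference: match, then gap in the first sequence, then
    # gap in the second - deterministic for tied optima
    i, j = n, m
    finals = {"M": M[n, m], "I": I[n, m], "D": D[n, m]}
    score = max(finals.values())
    state = next(s for s in "MID" if finals[s] >= score - _TOL)
    ops: list[str] = []
    while i > 0 or j > 0:
        ops.append(state)
        if state == "M":
            target = M[i, j] - colscore[i - 1, j - 1]
            i, j = i - 1, j - 1
            cand = {"M": M[i, j], "I": I[i, j], "D": D[i, j]}
        elif state == "I":
            target = I[i, j]
            j -= 1
            cand = {"M": M[i, j] - gop, "I": I[i, j] - gep, "D": D[i, j] - gop}
        else:
            target = D[i, j]
            i -= 1
            cand = {"M": M[i, j] - gop, "I": I[i, j] - gop, "D": D[i, j] - gep}
        if i == 0 and j == 0:
            break
        state = next(s for s in "MID" if cand[s] >= target - _TOL)
    ops.reverse()
    return float(score), "".join(ops)


def pairwise_affine_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix,
    gop: float,
    gep: float,
) -> tuple[Alignment, float]:
    """Optimal global alignment of two sequences under the affine model.

    The objective is sum of matrix scores over residue columns minus
    gop + (R - 1) * gep for every maximal gap run of length R.  Returns
    the alignment (rows named 'a' and 'b') and its score.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if gop < gep:
        warnings.warn(
            f"gap open penalty ({gop}) below gap extension penalty ({gep}); "
            "the affine model expects GOP > GEP",
            stacklevel=2,
        )
    idx, arr = _matrix_array(matrix)
    ea, eb = _encode(a, idx), _encode(b, idx)
    colscore = arr[np.ix_(ea, eb)]
    score, ops = _affine_dp(colscore, float(gop), float(gep))
    ra, rb, ia, ib = [], [], 0, 0
    for op in ops:
        if op == "M":
            ra.append(a[ia]); rb.append(b[ib]); ia += 1; ib += 1
        elif op == "D":
            ra.append(a[ia]); rb.append(GAP); ia += 1
        else:
            ra.append(GAP); rb.append(b[ib]); ib += 1
    aln = Alignment((("a", "".join(ra)), ("b", "".join(rb))))
    return aln, score


@dataclass(frozen=True)
class GuideTree:
    """Binary agglomeration tree over sequence ids.

    ``node`` is either a leaf id (str) or a (left, right, height) tuple.
    """

    node: object

    def leaves(self) -> tuple[str, ...]:
        out: list[str] = []

        def walk(n):
            if isinstance(n, str):
                out.append(n)
            else:
                walk(n[0].node)
                walk(n[1].node)

        walk(self.node)
        return tuple(out)


def upgma(distance: dict[tuple[str, str], float], ids: list[str]) -> GuideTree:
    """UPGMA agglomeration with deterministic lexicographic tie-breaking.

    ``distance`` maps unordered id pairs to distances.  Ties on distance
    are resolved toward the lexicographically smallest (label, label)
    pair, labels being each cluster's smallest leaf id.
    """
    clusters: dict[str, tuple[GuideTree, int]] = {
        i: (GuideTree(i), 1) for i in ids
    }
    dist = {}
    for x in ids:
        for y in ids:
            if x < y:
                dist[(x, y)] = distance[(x, y)] if (x, y) in distance else distance[(y, x)]
    while len(clusters) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (x, y), d = best
        tx, nx = clusters.pop(x)
        ty, ny = clusters.pop(y)
        merged = GuideTree((tx, ty, d / 2.0))
        label = min(x, y)
        newdist = {}
        for (p, q), v in dist.items():
            if x in (p, q) or y in (p, q):
                continue
            newdist[(p, q)] = v
        for z in clusters:
            dxz = dist[tuple(sorted((x, z)))]
            dyz = dist[tuple(sorted((y, z)))]
            v = (nx * dxz + ny * dyz) / (nx + ny)
            newdist[tuple(sorted((label, z)))] = v
        dist = newdist
        clusters[label] = (merged, nx + ny)
    (tree, _), = clusters.values()
    return tree


def build_guide_tree(
    seqs: SequenceSet,
    matrix: SubstitutionMatrix,
    gop: float,
    gep: float,
) -> GuideTree:
    """UPGMA tree on 1 - pairwise identity."""
    from .family_stats import pairwise_identity

    ids = list(seqs.ids)
    lookup = dict(seqs.records)
    dmat = {}
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            iden = pairwise_identity(lookup[x], lookup[y], matrix, gop, gep)
            dmat[tuple(sorted((x, y)))] = 1.0 - iden
    return upgma(dmat, ids)


def _profile(rows: list[str], idx: dict[str, int]) -> np.ndarray:
    """Per-column residue frequencies (L, |alphabet|); gaps carry no mass."""
    L = len(rows[0])
    prof = np.zeros((L, len(idx)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != GAP:
                prof[c, idx[ch]] += 1.0
    return prof / len(rows)


def _merge(
    left: list[tuple[str, str]],
    right: list[tuple[str, str]],
    ops: str,
) -> list[tuple[str, str]]:
    lrows = [list() for _ in left]
    rrows = [list() for _ in right]
    li = ri = 0
    for op in ops:
        if op in "MD":
            for k, (_, row) in enumerate(left):
                lrows[k].append(row[li])
            li += 1
        else:
            for k in range(len(left)):
                lrows[k].append(GAP)
        if op in "MI":
            for k, (_, row) in enumerate(right):
                rrows[k].append(row[ri])
            ri += 1
        else:
            for k in range(len(right)):
                rrows[k].append(GAP)
    out = [(sid, "".join(r)) for (sid, _), r in zip(left, lrows)]
    out += [(sid, "".join(r)) for (sid, _), r in zip(right, rrows)]
    return out


def progressive_align(
    seqs: SequenceSet,
    matrix: SubstitutionMatrix,
    gop: float,
    gep: float,
    tree: GuideTree | None = None,
) -> Alignment:
    """Progressive profile alignment along the guide tree.

    Profile-profile column gain is the expectation of the residue score
    under the product of column frequencies (gap mass scores zero), so
    the merge optimizes the same objective the SP score measures.  Gaps,
    once inserted, are never removed.
    """
    if tree is None:
        tree = build_guide_tree(seqs, matrix, gop, gep)
    idx, arr = _matrix_array(matrix)
    lookup = dict(seqs.records)

    def align_node(node) -> list[tuple[str, str]]:
        if isinstance(node.node, str):
            return [(node.node, lookup[node.node])]
        left = align_node(node.node[0])
        right = align_node(node.node[1])
        pl = _profile([r for _, r in left], idx)
        pr = _profile([r for _, r in right], idx)
        colscore = (pl @ arr) @ pr.T
        _, ops = _affine_dp(colscore, float(gop), float(gep))
        return _merge(left, right, ops)

    rows = align_node(tree)
    order = {sid: k for k, sid in enumerate(seqs.ids)}
    rows.sort(key=lambda r: order[r[0]])
    return Alignment(tuple(rows))
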