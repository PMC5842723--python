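"""Synthetic families, the parameter grid, and sweep/benchmark drivers.

The simulator evolves a random root protein down a star topology: each
of m descendants independently receives point substitutions and short
indels.  The event history implies the true multiple alignment, so every
simulated family ships with its own reference - the desk-scale analogue
of a curated benchmark family.

The sweep enumerates the study grid (GOP from 1 to 20 in steps of 1,
GEP from 0 in steps of 0.2 up to half of GOP, three BLOSUM matrices),
aligns the family at every parameter tuple, and scores each alignment
against the reference with SPS.  Alongside the grid it reports the
theory-estimated parameters and the fixed internal defaults
(GOP 10, GEP 1, BLOSUM62), so the three can be compared directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .aligner import progressive_align
from .family_stats import family_summary
from .io_formats import (
    BUNDLED_MATRICES,
    GAP,
    STANDARD_AA,
    Alignment,
    SequenceSet,
    load_matrix,
)
from .param_model import NonPositiveBoundError, ParamEstimate, auto_estimate
from .sp_objective import sps

logger = logging.getLogger(__name__)

#: Internal default alignment parameters used as the comparison baseline.
DEFAULT_GOP = 10.0
DEFAULT_GEP = 1.0
DEFAULT_MATRIX = "blosum62"

#: Insertion length distribution: short indels dominate in real families.
_INS_LEN = (1, 2, 3)
_INS_P = (0.6, 0.3, 0.1)


@dataclass(frozen=True)
class FamilyConfig:
    """Parameters of one simulated family.

    ``target_iden`` sets the aimed-for mean pairwise identity between
    descendants; the per-branch substitution probability is derived from
    it (two branches separate each pair, so per-branch conservation is
    about sqrt(identity)).  ``indel_rate`` is the total per-site
    probability of an indel event on a branch, split evenly between
    deletion and insertion.
    """

    m: int = 4
    root_len: int = 100
    target_iden: float = 0.4
    indel_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.root_len < 1:
            raise ValueError("root_len must be positive")
        if not 0.0 < self.target_iden <= 1.0:
            raise ValueError("target_iden must lie in (0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must lie in [0, 1]")

    @property
    def sub_rate(self) -> float:
        """Per-branch, per-site substitution probability implied by
        ``target_iden``."""
        return 1.0 - float(np.sqrt(self.target_iden))


@dataclass(frozen=True)
class SimulatedFamily:
    """A simulated family: unaligned sequences plus their true alignment."""

    seqs: SequenceSet
    truth: Alignment
    config: FamilyConfig
    realized_iden: float


def _truth_identity(truth: Alignment) -> float:
    """Mean pairwise identity read directly off the true alignment."""
    rows = truth.rows
    k = len(rows)
    vals = []
    for i in range(k):
        for j in range(i + 1, k):
            same = sum(
                1 for a, b in zip(rows[i], rows[j]) if a == b and a != GAP
            )
            denom = min(
                len(rows[i].replace(GAP, "")), len(rows[j].replace(GAP, ""))
            )
            vals.append(same / denom)
    return float(np.mean(vals))


def simulate_family(cfg: FamilyConfig, max_retries: int = 20) -> SimulatedFamily:
    """Evolve a family down a star topology and return it with its truth.

    Deterministic for a fixed config (the seed drives all randomness).
    Degenerate draws (a sequence deleted away entirely) are retried with
    a perturbed stream a bounded number of times.
    """
    for attempt in range(max_retries):
        rng = np.random.default_rng((cfg.seed, attempt))
        fam = _simulate_once(cfg, rng)
        if fam is not None:
            return fam
    raise RuntimeError(
        f"could not simulate a non-degenerate family after {max_retries} tries "
        f"(config {cfg})"
    )


def _simulate_once(cfg: FamilyConfig, rng: np.random.Generator) -> SimulatedFamily | None:
    aa = np.array(list(STANDARD_AA))
    root = rng.choice(aa, size=cfg.root_len)
    p_sub = cfg.sub_rate
    p_del = p_ins = cfg.indel_rate / 2.0

    kept = np.ones((cfg.m, cfg.root_len), dtype=bool)  # deletion mask
    residue = np.empty((cfg.m, cfg.root_len), dtype="<U1")
    # insertions[leaf][pos] = string inserted after root position pos
    insertions: list[dict[int, str]] = [dict() for _ in range(cfg.m)]
    for leaf in range(cfg.m):
        res = root.copy()
        sub_mask = rng.random(cfg.root_len) < p_sub
        for pos in np.flatnonzero(sub_mask):
            choices = aa[aa != res[pos]]
            res[pos] = rng.choice(choices)
        residue[leaf] = res
        kept[leaf] = rng.random(cfg.root_len) >= p_del
        ins_mask = rng.random(cfg.root_len) < p_ins
        for pos in np.flatnonzero(ins_mask):
            ln = rng.choice(_INS_LEN, p=_INS_P)
            insertions[leaf][int(pos)] = "".join(rng.choice(aa, size=ln))

    # assemble truth columns: each root position, then that position's
    # insertion columns in leaf order
    cols: list[list[str]] = []
    for pos in range(cfg.root_len):
        col = [
            residue[leaf, pos] if kept[leaf, pos] else GAP
            for leaf in range(cfg.m)
        ]
        if any(c != GAP for c in col):  # drop columns deleted in every leaf
            cols.append(col)
        for leaf in range(cfg.m):
            ins = insertions[leaf].get(pos, "")
            for ch in ins:
                cols.append([ch if k == leaf else GAP for k in range(cfg.m)])
    rows = ["".join(col[leaf] for col in cols) for leaf in range(cfg.m)]
    if any(set(r) == {GAP} or not r.replace(GAP, "") for r in rows):
        return None
    records = tuple((f"seq{leaf + 1}", rows[leaf]) for leaf in range(cfg.m))
    truth = Alignment(records)
    seqs = truth.ungapped()
    return SimulatedFamily(
        seqs=seqs, truth=truth, config=cfg, realized_iden=_truth_identity(truth)
    )


def grid(
    gop_min: int = 1,
    gop_max: int = 20,
    gop_step: int = 1,
    gep_step: float = 0.2,
    matrices: Sequence[str] = BUNDLED_MATRICES,
) -> list[tuple[float, float, str]]:
    """Enumerate the sweep grid as (gop, gep, matrix_name) tuples.

    GEP runs from 0 in ``gep_step`` increments while staying strictly
    below GOP/2; with the default bounds and all three matrices this
    yields exactly 1,590 combinations.
    """
    if gop_min <= 0 or gop_step <= 0 or gep_step <= 0:
        raise ValueError("grid bounds and steps must be positive")
    combos: list[tuple[float, float, str]] = []
    for name in matrices:
        for gop in range(gop_min, gop_max + 1, gop_step):
            k = 0
            while k * gep_step < gop / 2.0 - 1e-9:
                combos.append((float(gop), round(k * gep_step, 10), name))
                k += 1
    return combos


@dataclass(frozen=True)
class SweepRow:
    gop: float
    gep: float
    matrix_name: str
    sps: float | None
    label: str = "grid"


@dataclass(frozen=True)
class SweepResult:
    rows: tuple[SweepRow, ...]
    estimate: ParamEstimate | None = None

    def best(self) -> SweepRow:
        scored = [r for r in self.rows if r.sps is not None]
        if not scored:
            raise ValueError("no scored rows in sweep")
        return max(scored, key=lambda r: (r.sps, -r.gop, -r.gep))

    def labelled(self, label: str) -> SweepRow | None:
        for r in self.rows:
            if r.label == label:
                return r
        return None


def _align_and_score(
    seqs: SequenceSet, ref: Alignment, gop: float, gep: float, matrix_name: str
) -> float:
    matrix = load_matrix(matrix_name)
    aln = progressive_align(seqs, matrix, gop, gep)
    return sps(aln, ref)


def sweep(
    seqs: SequenceSet,
    ref: Alignment,
    params: Iterable[tuple[float, float, str]],
    include_theory: bool = True,
    include_default: bool = True,
) -> SweepResult:
    """Align the family at every parameter tuple and score against ``ref``.

    Appends the theory-parameter row (estimated from the family itself)
    and the internal-default row.  Per-tuple failures are logged and
    recorded with a missing score, never fatal.
    """
    rows: list[SweepRow] = []
    for gop, gep, name in params:
        try:
            value = _align_and_score(seqs, ref, gop, gep, name)
        except Exception:
            logger.exception("sweep point failed: gop=%s gep=%s %s", gop, gep, name)
            value = None
        rows.append(SweepRow(gop=gop, gep=gep, matrix_name=name, sps=value))
    estimate = None
    if include_theory:
        try:
            estimate = auto_estimate(family_summary(seqs))
            value = _align_and_score(
                seqs, ref, estimate.gop, estimate.gep, estimate.matrix_name
            )
            rows.append(
                SweepRow(
                    gop=estimate.gop,
                    gep=estimate.gep,
                    matrix_name=estimate.matrix_name,
                    sps=value,
                    label="theory",
                )
            )
        except NonPositiveBoundError:
            logger.exception("theory estimate unavailable for this family")
    if include_default:
        value = _align_and_score(seqs, ref, DEFAULT_GOP, DEFAULT_GEP, DEFAULT_MATRIX)
        rows.append(
            SweepRow(
                gop=DEFAULT_GOP,
                gep=DEFAULT_GEP,
                matrix_name=DEFAULT_MATRIX,
                sps=value,
                label="default",
            )
        )
    return SweepResult(rows=tuple(rows), estimate=estimate)


def report(result: SweepResult) -> dict:
    """Summarize a sweep: per-matrix best, overall best, theory vs default."""
    if not result.rows:
        raise ValueError("empty sweep")
    per_matrix: dict[str, SweepRow] = {}
    for r in result.rows:
        if r.label != "grid" or r.sps is None:
            continue
        cur = per_matrix.get(r.matrix_name)
        if cur is None or r.sps > cur.sps:
            per_matrix[r.matrix_name] = r
    theory = result.labelled("theory")
    default = result.labelled("default")
    summary = {
        "per_matrix_best": {
            k: {"gop": v.gop, "gep": v.gep, "sps": v.sps}
            for k, v in sorted(per_matrix.items())
        },
        "best": None,
        "theory": None,
        "default": None,
        "theory_minus_default": None,
    }
    scored = [r for r in result.rows if r.sps is not None]
    if scored:
        b = result.best()
        summary["best"] = {
            "gop": b.gop, "gep": b.gep, "matrix": b.matrix_name,
            "sps": b.sps, "label": b.label,
        }
    if theory is not None and theory.sps is not None:
        summary["theory"] = {
            "gop": theory.gop, "gep": theory.gep,
            "matrix": theory.matrix_name, "sps": theory.sps,
        }
    if default is not None and default.sps is not None:
        summary["default"] = {
            "gop": default.gop, "gep": default.gep,
            "matrix": default.matrix_name, "sps": default.sps,
        }
    if summary["theory"] and summary["default"]:
        summary["theory_minus_default"] = (
            summary["theory"]["sps"] - summary["default"]["sps"]
        )
    return summary


def sweep_to_tsv(result: SweepResult) -> str:
    lines = ["label\tmatrix\tgop\tgep\tsps"]
    for r in result.rows:
        value = "" if r.sps is None else f"{r.sps:.6f}"
        lines.append(f"{r.label}\t{r.matrix_name}\t{r.gop:g}\t{r.gep:g}\t{value}")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class BenchRecord:
    seed: int
    m: int
    realized_iden: float
    theory_sps: float
    default_sps: float
    estimate: ParamEstimate


def bench(
    n_families: int = 20,
    seed: int = 1,
    target_idens: Sequence[float] = (0.2, 0.3, 0.4, 0.5, 0.6),
    ms: Sequence[int] = (4, 5),
    root_lens: Sequence[int] = (60, 100, 150),
    indel_rate: float = 0.05,
) -> list[BenchRecord]:
    """Theory-vs-default comparison over seeded synthetic families.

    For each family the theory parameters come from the family's own
    statistics (preset + penalty estimate); the baseline is the fixed
    internal default.  Both alignments are scored with SPS against the
    simulation truth.
    """
    rng = np.random.default_rng(seed)
    records: list[BenchRecord] = []
    i = 0
    while len(records) < n_families:
        cfg = FamilyConfig(
            m=int(rng.choice(ms)),
            root_len=int(rng.choice(root_lens)),
            target_iden=float(rng.choice(target_idens)),
            indel_rate=indel_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        i += 1
        fam = simulate_family(cfg)
        try:
            est = auto_estimate(family_summary(fam.seqs))
        except NonPositiveBoundError:
            logger.warning("skipping family with degenerate statistics: %s", cfg)
            continue
        theory_sps = _align_and_score(
            fam.seqs, fam.truth, est.gop, est.gep, est.matrix_name
        )
        default_sps = _align_and_score(
            fam.seqs, fam.truth, DEFAULT_GOP, DEFAULT_GEP, DEFAULT_MATRIX
        )
        records.append(
            BenchRecord(
                seed=cfg.seed,
                m=cfg.m,
                realized_iden=fam.realized_iden,
                theory_sps=theory_sps,
                default_sps=default_sps,
                estimate=est,
            )
        )
    return records
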