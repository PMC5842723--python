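"""Readers and writers for the formats the tool touches.

Unaligned and aligned FASTA, GCG MSF reference alignments (the format
BAliBASE-style benchmarks ship), and plain-text substitution matrices in
the whitespace-separated NCBI/EMBOSS layout.  The gap character is
canonicalized to ``'-'`` everywhere; ``'.'`` and ``'~'`` are accepted on
input only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from Bio import AlignIO, SeqIO

#: The 20 standard amino acids, in the conventional matrix order.
STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguity codes tolerated in sequences and matrices.
AMBIGUOUS_AA = "BZX"

_VALID_RESIDUES = frozenset(STANDARD_AA + AMBIGUOUS_AA)

GAP = "-"

#: Names of the substitution-matrix tables bundled with the package.
BUNDLED_MATRICES = ("blosum30", "blosum45", "blosum62")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceSet:
    """An ordered family of named, unaligned protein sequences.

    Invariants: at least two records, unique ids, non-empty residue
    strings over the 20 amino acids plus B/Z/X, and no gap characters.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("a sequence family needs at least 2 records")
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id: {dup!r}")
        for sid, res in self.records:
            if not res:
                raise ValueError(f"empty sequence: {sid!r}")
            bad = set(res) - _VALID_RESIDUES
            if bad:
                raise ValueError(
                    f"sequence {sid!r} contains invalid residue letters: "
                    f"{sorted(bad)} (gaps are not allowed in unaligned input)"
                )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(r[1] for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows over the residue alphabet plus ``'-'``."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        length = len(self.records[0][1])
        if length < 1:
            raise ValueError("alignment has zero columns")
        for sid, row in self.records:
            if len(row) != length:
                raise ValueError(
                    f"ragged alignment: row {sid!r} has length {len(row)}, "
                    f"expected {length}"
                )
            if set(row) == {GAP}:
                raise ValueError(f"row {sid!r} is all gaps")
            bad = set(row) - _VALID_RESIDUES - {GAP}
            if bad:
                raise ValueError(f"row {sid!r} contains invalid letters: {sorted(bad)}")
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def length(self) -> int:
        """Number of columns L."""
        return len(self.records[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.records)

    @property
    def rows(self) -> tuple[str, ...]:
        return tuple(r[1] for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def ungapped(self) -> SequenceSet:
        """Strip gaps from every row, recovering the input family."""
        return SequenceSet(
            tuple((sid, row.replace(GAP, "")) for sid, row in self.records)
        )


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue-pair score lookup.

    ``scores`` maps unordered residue pairs to integers; the 20 standard
    amino acids are always present, ambiguity codes may be.
    """

    name: str
    alphabet: tuple[str, ...]
    scores: Mapping[tuple[str, str], int] = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(STANDARD_AA) - set(self.alphabet)
        if missing:
            raise ValueError(
                f"matrix {self.name!r} is missing standard amino acids: "
                f"{sorted(missing)}"
            )

    def score(self, a: str, b: str) -> int:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise KeyError(
                f"matrix {self.name!r} has no score for residue pair ({a!r}, {b!r})"
            ) from None


def _canonical_row(row: str) -> str:
    return row.upper().replace(".", GAP).replace("~", GAP)


def read_fasta(path: str | Path) -> SequenceSet:
    """Read unaligned FASTA into a :class:`SequenceSet`.

    Whitespace is stripped and letters upper-cased.  Gap characters are a
    hard error: aligned input belongs to :func:`read_aligned_fasta`.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id in {path}: {rec.id!r}")
        seen.add(rec.id)
        residues = "".join(str(rec.seq).split()).upper()
        if not residues:
            raise FormatError(f"empty sequence in {path}: {rec.id!r}")
        if any(c in residues for c in "-.~"):
            raise FormatError(
                f"sequence {rec.id!r} in {path} contains gap characters; "
                "use read_aligned_fasta for aligned input"
            )
        records.append((rec.id, residues))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return SequenceSet(tuple(records))


def read_aligned_fasta(path: str | Path) -> Alignment:
    """Read gapped FASTA where every record has the same length."""
    records: list[tuple[str, str]] = []
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        row = _canonical_row("".join(str(rec.seq).split()))
        if length is None:
            length = len(row)
        elif len(row) != length:
            raise FormatError(
                f"ragged alignment in {path}: record {rec.id!r} has length "
                f"{len(row)}, expected {length}"
            )
        records.append((rec.id, row))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment(tuple(records))


def read_msf(path: str | Path) -> Alignment:
    """Read a GCG MSF alignment (the BAliBASE reference format).

    ``'.'`` and ``'~'`` gaps become ``'-'``; the row contract matches
    :func:`read_aligned_fasta`.
    """
    text = Path(path).read_text()
    header = text.split("//", 1)[0]
    if not any("MSF:" in ln and ln.rstrip().endswith("..") for ln in header.splitlines()):
        raise FormatError(f"{path} lacks the 'MSF: ... ..' header sentinel")
    try:
        msa = AlignIO.read(str(path), "msf")
    except ValueError as exc:
        raise FormatError(f"malformed MSF file {path}: {exc}") from exc
    return Alignment(
        tuple((rec.id, _canonical_row(str(rec.seq))) for rec in msa)
    )


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, res in seqs.records:
            fh.write(f">{sid}\n")
            for i in range(0, len(res), width):
                fh.write(res[i : i + width] + "\n")


def write_aligned_fasta(aln: Alignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, row in aln.records:
            fh.write(f">{sid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def parse_score_matrix(text: str, name: str = "custom") -> SubstitutionMatrix:
    """Parse an NCBI/EMBOSS whitespace-separated substitution matrix.

    The first non-comment line is the column alphabet; each following line
    is a row letter and its integer scores.  The parsed lookup must be
    exactly symmetric and cover the 20 standard amino acids.
    """
    lines = [
        ln for ln in io.StringIO(text) if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise FormatError("empty matrix text")
    header = lines[0].split()
    columns = [c.upper() for c in header]
    scores: dict[tuple[str, str], int] = {}
    row_letters: list[str] = []
    for ln in lines[1:]:
        parts = ln.split()
        letter = parts[0].upper()
        cells = parts[1 : 1 + len(columns)]
        if len(cells) != len(columns):
            raise FormatError(
                f"matrix row {letter!r} has {len(cells)} cells, "
                f"expected {len(columns)}"
            )
        row_letters.append(letter)
        for col, cell in zip(columns, cells):
            try:
                scores[(letter, col)] = int(cell)
            except ValueError:
                raise FormatError(
                    f"non-integer matrix cell {cell!r} at ({letter}, {col})"
                ) from None
    # keep letters we can actually look up both ways; '*' columns are dropped
    alphabet = tuple(c for c in columns if c in row_letters and c != "*")
    missing = set(STANDARD_AA) - set(alphabet)
    if missing:
        raise FormatError(f"matrix is missing standard amino acids: {sorted(missing)}")
    for a in alphabet:
        for b in alphabet:
            if scores[(a, b)] != scores[(b, a)]:
                raise FormatError(
                    f"asymmetric matrix: score({a},{b})={scores[(a, b)]} but "
                    f"score({b},{a})={scores[(b, a)]}"
                )
    table = {
        (a, b): scores[(a, b)] for a in alphabet for b in alphabet
    }
    return SubstitutionMatrix(name=name, alphabet=alphabet, scores=table)


def load_matrix(name: str) -> SubstitutionMatrix:
    """Load a bundled matrix by name (``blosum30``, ``blosum45``, ``blosum62``)."""
    key = name.lower()
    if key not in BUNDLED_MATRICES:
        raise KeyError(
            f"unknown matrix {name!r}; bundled: {', '.join(BUNDLED_MATRICES)}"
        )
    text = resources.files("msaparam.data").joinpath(f"{key}.txt").read_text()
    return parse_score_matrix(text, name=key)


def read_matrix_file(path: str | Path) -> SubstitutionMatrix:
    p = Path(path)
    return parse_score_matrix(p.read_text(), name=p.stem)
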