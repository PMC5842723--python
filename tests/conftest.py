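import textwrap

import pytest

from msaparam.io_formats import SubstitutionMatrix, load_matrix

STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"


def toy_matrix(diag: int = 5, off: int = -1) -> SubstitutionMatrix:
    """Identity-like 20x20 matrix: ``diag`` on the diagonal, ``off`` elsewhere."""
    letters = tuple(STANDARD_AA)
    scores = {
        (a, b): (diag if a == b else off) for a in letters for b in letters
    }
    return SubstitutionMatrix(name=f"toy{diag}{off}", alphabet=letters, scores=scores)


@pytest.fixture(scope="session")
def toy():
    return toy_matrix()


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("blosum62")


@pytest.fixture(scope="session")
def blosum45():
    return load_matrix("blosum45")


@pytest.fixture(scope="session")
def blosum30():
    return load_matrix("blosum30")


@pytest.fixture
def fasta_file(tmp_path):
    def write(text: str, name: str = "in.fasta"):
        p = tmp_path / name
        p.write_text(textwrap.dedent(text))
        return p

    return write


MSF_TEXT = """\
PileUp

 MSF: 12  Type: P  Check: 0 ..

 Name: s1 oo  Len: 12  Check: 0  Weight: 1.0
 Name: s2 oo  Len: 12  Check: 0  Weight: 1.0

//

s1  ACDEF GHIK.  LM
s2  AC.EF GH~KW  LM
"""

FASTA_TWIN = """\
>s1
ACDEFGHIK-LM
>s2
AC-EFGH-KWLM
"""


@pytest.fixture
def msf_pair(tmp_path):
    """A minimal MSF file and its aligned-FASTA twin."""
    msf = tmp_path / "ref.msf"
    msf.write_text(MSF_TEXT)
    fasta = tmp_path / "ref.fasta"
    fasta.write_text(FASTA_TWIN)
    return msf, fasta
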