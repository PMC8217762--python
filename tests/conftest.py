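import numpy as np
import pytest

from famevo.io_formats import AlignmentSet

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_protein(rng):
    def make(length: int) -> str:
        return "".join(AA[i] for i in rng.integers(0, 20, size=length))

    return make


@pytest.fixture
def small_alignment():
    """Four taxa; columns 1-4 separate {A,B} from {C,D}, column 5 shared."""
    return AlignmentSet(
        ["A", "B", "C", "D"],
        ["AAAAG", "AAAAG", "CCCCG", "CCCCG"],
    )


@pytest.fixture
def domtbl_text():
    header = "#" + " tbl" * 3 + "\n# --- --- ---\n"
    cols = [
        "prot{i}", "-", "Wnt", "PF00110.20", "PF00110", "350",
        "{ev}", "{sc}", "1.2", "1", "1", "1.0e-07", "{iev}", "49.0", "0.9",
        "5", "320", "4", "330", "{envf}", "{envt}", "0.95", "desc here",
    ]

    def line(i, ev, sc, iev="2.0e-07", envf="4", envt="330"):
        vals = " ".join(cols).format(i=i, ev=ev, sc=sc, iev=iev, envf=envf, envt=envt)
        return vals + "\n"

    return header, line
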