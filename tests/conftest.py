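import pytest

from rnacleave import (
    RnaSequence,
    SecondaryStructure,
    builtin_enzyme,
    parse_dotbracket,
)


@pytest.fixture
def hairpin():
    """A 7-nt hairpin: two closing pairs around a 3-nt loop."""
    return parse_dotbracket("GGAAACC\n((...))")


@pytest.fixture
def unstructured():
    """A fully single-stranded 7-mer."""
    return parse_dotbracket("AGCAUGG\n.......")


@pytest.fixture
def t1():
    return builtin_enzyme("T1")


@pytest.fixture
def rnase_a():
    return builtin_enzyme("A")


@pytest.fixture
def v1():
    return builtin_enzyme("V1")


@pytest.fixture
def t2():
    return builtin_enzyme("T2")


def make_structure(residues: str, dotbracket: str) -> SecondaryStructure:
    return parse_dotbracket(f"{residues}\n{dotbracket}")
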